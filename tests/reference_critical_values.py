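"""Published reference critical values (minimum confidence) for n = 1000.

Layout: CRITICAL_VALUES[(p2, level, p1)] -> minimum confidence, for
p1, p2 in {0.1, 0.3, 0.5, 0.7, 0.9} and levels 80/90/95/99 %.
"""

_P1 = (0.1, 0.3, 0.5, 0.7, 0.9)

_ROWS = {
    (0.1, 0.80): (0.1245, 0.1135, 0.1105, 0.1095, 0.1075),
    (0.1, 0.90): (0.1395, 0.1225, 0.1165, 0.1145, 0.1125),
    (0.1, 0.95): (0.1515, 0.1285, 0.1225, 0.1185, 0.1165),
    (0.1, 0.99): (0.1755, 0.1415, 0.1315, 0.1265, 0.1235),
    (0.3, 0.80): (0.3385, 0.3215, 0.3165, 0.3145, 0.3125),
    (0.3, 0.90): (0.3585, 0.3335, 0.3255, 0.3215, 0.3195),
    (0.3, 0.95): (0.3755, 0.3435, 0.3335, 0.3285, 0.3245),
    (0.3, 0.99): (0.4095, 0.3625, 0.3475, 0.3405, 0.3355),
    (0.5, 0.80): (0.5415, 0.5235, 0.5185, 0.5155, 0.5135),
    (0.5, 0.90): (0.5635, 0.5365, 0.5285, 0.5235, 0.5205),
    (0.5, 0.95): (0.5825, 0.5475, 0.5365, 0.5305, 0.5265),
    (0.5, 0.99): (0.6165, 0.5665, 0.5515, 0.5435, 0.5385),
    (0.7, 0.80): (0.7385, 0.7215, 0.7165, 0.7145, 0.7125),
    (0.7, 0.90): (0.7585, 0.7335, 0.7255, 0.7215, 0.7195),
    (0.7, 0.95): (0.7745, 0.7425, 0.7325, 0.7275, 0.7245),
    (0.7, 0.99): (0.8035, 0.7605, 0.7465, 0.7395, 0.7345),
    (0.9, 0.80): (0.9255, 0.9145, 0.9105, 0.9095, 0.9075),
    (0.9, 0.90): (0.9375, 0.9215, 0.9165, 0.9135, 0.9125),
    (0.9, 0.95): (0.9465, 0.9275, 0.9215, 0.9175, 0.9155),
    (0.9, 0.99): (0.9635, 0.9375, 0.9295, 0.9255, 0.9225),
}

CRITICAL_VALUES = {
    (p2, level, p1): v
    for (p2, level), row in _ROWS.items()
    for p1, v in zip(_P1, row)
}
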