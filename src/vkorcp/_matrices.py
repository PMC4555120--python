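"""Published amino-acid replacement matrices.

Exchangeabilities are stored as the flattened lower triangle of the symmetric
20x20 matrix, column-major over the standard PAML residue order
(A R N D C Q E G H I L K M F P S T W Y V): entries (i, j) with j < i, j
ascending and, within a column, i ascending.  Equilibrium frequencies follow
the same residue order.

WAG: Whelan & Goldman (2001), Mol Biol Evol 18:691.
JTT: Jones, Taylor & Thornton (1992), CABIOS 8:275.
"""

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

WAG_EXCHANGEABILITIES = (
    0.551571, 0.509848, 0.738998, 1.02704, 0.908598,
    1.58285, 1.41672, 0.316954, 0.193335, 0.397915,
    0.906265, 0.893496, 0.210494, 1.43855, 3.37079,
    2.12111, 0.113133, 0.240735, 2.00601, 0.635346,
    0.147304, 0.528191, 3.0355, 0.439157, 0.584665,
    2.13715, 0.186979, 0.497671, 5.35142, 0.683162,
    0.102711, 0.679489, 1.22419, 0.554413, 1.16392,
    0.381533, 0.251849, 5.42942, 0.265256, 1.54364,
    0.947198, 1.12556, 3.95629, 0.554236, 0.131528,
    3.01201, 0.198221, 0.0961621, 0.195081, 3.97423,
    2.03006, 0.0719167, 1.086, 0.196246, 0.0302949,
    0.616783, 6.17416, 0.865584, 0.930676, 0.039437,
    0.0848047, 0.479855, 0.103754, 0.0467304, 0.423984,
    1.07176, 0.374866, 0.129767, 0.325711, 0.152335,
    0.0988179, 0.021352, 0.306674, 0.248972, 0.170135,
    0.384287, 0.0740339, 0.390482, 0.39802, 0.109404,
    1.40766, 0.512984, 0.71707, 0.543833, 1.00214,
    5.46947, 0.330052, 4.29411, 0.113917, 0.869489,
    3.8949, 1.54526, 0.0999208, 0.933372, 1.02887,
    0.857928, 0.215737, 0.22771, 0.301281, 0.567717,
    0.570025, 0.127395, 0.154263, 2.58443, 0.315124,
    0.0811339, 0.682355, 0.704939, 0.822765, 0.156557,
    0.196303, 0.588731, 0.24941, 0.0304501, 0.0613037,
    0.373558, 0.1741, 0.049931, 0.24357, 1.34182,
    0.225833, 0.336983, 0.103604, 0.187247, 0.13819,
    0.499462, 0.890432, 0.404141, 0.679371, 0.696198,
    0.740169, 0.473307, 0.262569, 3.87344, 0.118358,
    3.17097, 0.323832, 4.25746, 1.05947, 0.0999288,
    0.31944, 1.45816, 0.212483, 0.42017, 7.8213,
    0.257555, 4.85402, 2.11517, 0.415844, 0.344739,
    0.326622, 0.665309, 0.398618, 1.80034, 0.934276,
    0.088836, 0.556896, 0.96713, 1.38698, 0.137505,
    0.133264, 0.305434, 1.19063, 0.171329, 0.493905,
    1.51612, 0.515706, 0.428437, 2.05845, 0.161444,
    0.545931, 0.171903, 1.52964, 6.45428, 0.649892,
    1.61328, 0.795384, 0.139405, 0.216046, 0.314887,
    4.37802, 0.523742, 0.786993, 0.232739, 0.110864,
    0.291148, 1.38823, 2.48539, 0.365369, 0.31473,
)

WAG_FREQUENCIES = (
    0.08662790866, 0.0439720044, 0.03908940391, 0.0570451057, 0.01930780193,
    0.03672810367, 0.05805890581, 0.08325180833, 0.02443130244, 0.04846600485,
    0.08620900862, 0.0620286062, 0.01950270195, 0.03843190384, 0.04576310458,
    0.06951790695, 0.0610127061, 0.01438590144, 0.03527420353, 0.07089560709,
)

JTT_EXCHANGEABILITIES = (
    58.0, 54.0, 81.0, 56.0, 57.0,
    105.0, 179.0, 27.0, 36.0, 30.0,
    35.0, 54.0, 15.0, 194.0, 378.0,
    475.0, 9.0, 11.0, 298.0, 45.0,
    16.0, 113.0, 310.0, 29.0, 137.0,
    328.0, 22.0, 38.0, 646.0, 44.0,
    5.0, 74.0, 101.0, 64.0, 126.0,
    20.0, 17.0, 528.0, 34.0, 86.0,
    58.0, 81.0, 391.0, 47.0, 12.0,
    263.0, 30.0, 10.0, 15.0, 503.0,
    232.0, 8.0, 70.0, 16.0, 10.0,
    49.0, 767.0, 130.0, 112.0, 11.0,
    7.0, 26.0, 15.0, 4.0, 15.0,
    59.0, 38.0, 4.0, 46.0, 31.0,
    9.0, 5.0, 59.0, 69.0, 17.0,
    23.0, 7.0, 31.0, 78.0, 14.0,
    223.0, 42.0, 115.0, 209.0, 62.0,
    323.0, 26.0, 597.0, 9.0, 72.0,
    292.0, 43.0, 4.0, 164.0, 53.0,
    51.0, 18.0, 24.0, 20.0, 119.0,
    26.0, 12.0, 9.0, 181.0, 18.0,
    5.0, 18.0, 30.0, 32.0, 10.0,
    7.0, 45.0, 23.0, 6.0, 6.0,
    27.0, 14.0, 5.0, 24.0, 201.0,
    33.0, 55.0, 8.0, 47.0, 16.0,
    56.0, 45.0, 33.0, 40.0, 115.0,
    73.0, 46.0, 8.0, 573.0, 11.0,
    229.0, 21.0, 479.0, 89.0, 10.0,
    40.0, 245.0, 9.0, 32.0, 961.0,
    14.0, 388.0, 248.0, 102.0, 59.0,
    25.0, 52.0, 24.0, 180.0, 65.0,
    4.0, 21.0, 47.0, 103.0, 10.0,
    8.0, 14.0, 43.0, 16.0, 29.0,
    226.0, 24.0, 18.0, 323.0, 17.0,
    92.0, 12.0, 53.0, 536.0, 62.0,
    285.0, 118.0, 6.0, 10.0, 23.0,
    477.0, 35.0, 63.0, 38.0, 12.0,
    21.0, 112.0, 71.0, 25.0, 16.0,
)

JTT_FREQUENCIES = (
    0.07674792325, 0.05169094831, 0.04264495736, 0.05154394846, 0.0198029802,
    0.04075195925, 0.06182993817, 0.07315192685, 0.02294397706, 0.05376094624,
    0.0919039081, 0.05867594132, 0.02382597617, 0.04012595987, 0.0509009491,
    0.06876493124, 0.05856494144, 0.01426098574, 0.0321019679, 0.066004934,
)

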