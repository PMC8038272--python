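"""Published RULA look-up tables (McAtamney & Corlett, 1993).

``TABLE_B`` combines the neck posture score (rows, 1-6) with the trunk
posture score (columns, 1-6) and the legs/feet support score (last axis:
1 = supported and evenly balanced, 2 = not) into the section-B score for
head and trunk.  Entries are monotone non-decreasing in every argument;
the table's maximum is 9 and scores >= 7 are reachable even with
supported legs.

``TABLE_C`` is the grand-score table combining the arm-and-wrist section
score (rows, 1-8, last row meaning "8 or more") with the neck-trunk-legs
section score (columns, 1-7, last column meaning "7 or more") into the
final RULA score 1-7.

Values are transcribed from the published worksheets; checksum tests pin
them (sum of TABLE_B = 438, sum of TABLE_C = 269).
"""

import numpy as np

# shape (neck 1-6, trunk 1-6, legs 1-2)
TABLE_B = np.array([
    [[1, 3], [2, 3], [3, 4], [5, 5], [6, 6], [7, 7]],
    [[2, 3], [2, 3], [4, 5], [5, 5], [6, 7], [7, 7]],
    [[3, 3], [3, 4], [4, 5], [5, 6], [6, 7], [7, 7]],
    [[5, 5], [5, 6], [6, 7], [7, 7], [7, 7], [8, 8]],
    [[7, 7], [7, 7], [7, 8], [8, 8], [8, 8], [8, 8]],
    [[8, 8], [8, 8], [8, 8], [8, 9], [9, 9], [9, 9]],
], dtype=int)

# shape (arm/wrist score 1-8+, neck/trunk/legs score 1-7+)
TABLE_C = np.array([
    [1, 2, 3, 3, 4, 5, 5],
    [2, 2, 3, 4, 4, 5, 5],
    [3, 3, 3, 4, 4, 5, 6],
    [3, 3, 3, 4, 5, 6, 6],
    [4, 4, 4, 5, 6, 7, 7],
    [4, 4, 5, 6, 6, 7, 7],
    [5, 5, 6, 6, 7, 7, 7],
    [5, 5, 6, 7, 7, 7, 7],
], dtype=int)
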