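"""Worked-example inputs: a published 7-cluster interaction-map solution.

Cluster centers (mean item positions per cluster) and four person records
from an inductive-reasoning test analysis, printed to 3 decimal places.
The analytics must reproduce the printed pairwise distances from these
rounded inputs to within +/-0.005.
"""

import numpy as np

# cluster id -> (center dim1, center dim2)
CLUSTER_CENTERS = np.array(
    [
        [0.168, -0.174],
        [-0.207, -0.733],
        [-0.685, 0.120],
        [-1.828, 0.529],
        [0.758, 2.065],
        [1.613, -0.471],
        [1.570, -1.840],
    ]
)

# printed upper-triangle inter-cluster distances, keyed (row, col) 1-based
CLUSTER_DISTANCES = {
    (1, 2): 0.673, (1, 3): 0.902, (1, 4): 2.116, (1, 5): 2.316, (1, 6): 1.476, (1, 7): 2.178,
    (2, 3): 0.977, (2, 4): 2.054, (2, 5): 2.960, (2, 6): 1.840, (2, 7): 2.094,
    (3, 4): 1.214, (3, 5): 2.422, (3, 6): 2.373, (3, 7): 2.988,
    (4, 5): 3.008, (4, 6): 3.584, (4, 7): 4.143,
    (5, 6): 2.677, (5, 7): 3.989,
    (6, 7): 1.370,
}

# person id -> (theta_hat, position, distances to clusters 1..7, accuracy)
PERSON_RECORDS = {
    "64": {
        "theta": 1.043,
        "position": np.array([-1.227, 0.656]),
        "cluster_distances": np.array([1.622, 1.723, 0.762, 0.615, 2.434, 3.055, 3.749]),
        "accuracy": 0.571,
    },
    "1359": {
        "theta": 1.155,
        "position": np.array([-1.285, 1.016]),
        "cluster_distances": np.array([1.877, 2.054, 1.078, 0.730, 2.296, 3.257, 4.038]),
        "accuracy": 0.571,
    },
    "1653": {
        "theta": 1.227,
        "position": np.array([1.015, -1.775]),
        "cluster_distances": np.array([1.812, 1.607, 2.546, 3.660, 3.849, 1.435, 0.559]),
        "accuracy": 0.411,
    },
    "1655": {
        "theta": 1.060,
        "position": np.array([1.424, -0.976]),
        "cluster_distances": np.array([1.491, 1.650, 2.377, 3.584, 3.113, 0.539, 0.877]),
        "accuracy": 0.446,
    },
}
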