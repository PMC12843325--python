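"""Published CASIA-B reference results for the skeletal-template method.

Cross-view rank-1 matrices (normal-walking gallery vs. normal-walking
probe) for the joint-based skeletal template and the silhouette energy
image under the seven-view protocol (0, 36, 72, 90, 108, 144, 180 degrees),
together with the same-view covariate means.  Rows are gallery views,
columns probe views, values in percent.  These tables serve as worked
inputs for the aggregation arithmetic in :mod:`gsigait.recognition`
(:func:`summarize_matrix`, :func:`covariate_report`); the package does not
attempt to reproduce the absolute accuracies themselves, which require the
CASIA-B recordings.

``*_PRINTED_COL_MEANS`` are the column means as printed in the source
tables.  The printed 90-degree column mean of the joint-template matrix
(30.01) is inconsistent with its own column entries, which average 31.43;
aggregations in this package always recompute means from the entries.
"""

import numpy as np

__all__ = [
    "CASIA_B_VIEWS",
    "GSI_JOINTS_CROSS_VIEW",
    "GEI_CROSS_VIEW",
    "GSI_JOINTS_PRINTED_COL_MEANS",
    "GEI_PRINTED_COL_MEANS",
    "SAME_VIEW_COVARIATE_MEANS",
]

CASIA_B_VIEWS = (0, 36, 72, 90, 108, 144, 180)

GSI_JOINTS_CROSS_VIEW = np.array(
    [
        [75.26, 11.81, 8.55, 9.43, 12.14, 9.93, 31.77],
        [18.53, 72.96, 23.44, 10.26, 16.63, 18.33, 4.85],
        [10.33, 18.65, 74.21, 54.66, 49.77, 9.70, 5.10],
        [10.89, 8.14, 57.78, 77.20, 50.42, 8.61, 9.16],
        [11.57, 12.67, 45.70, 51.83, 74.48, 25.81, 10.78],
        [9.61, 26.92, 8.45, 7.20, 28.47, 74.13, 13.08],
        [33.26, 8.29, 6.47, 9.47, 11.47, 18.80, 74.96],
    ]
)

GEI_CROSS_VIEW = np.array(
    [
        [98.28, 6.10, 0.47, 0.16, 1.10, 3.60, 31.77],
        [10.49, 96.40, 19.72, 9.23, 10.64, 28.33, 4.85],
        [2.50, 15.65, 96.09, 84.66, 49.77, 9.70, 1.10],
        [1.25, 8.14, 77.78, 97.18, 70.42, 8.61, 1.56],
        [1.72, 7.67, 50.70, 71.83, 95.62, 15.81, 0.78],
        [5.48, 26.92, 8.45, 7.20, 18.47, 96.40, 9.08],
        [34.12, 3.29, 0.47, 0.47, 0.47, 10.80, 98.28],
    ]
)

GSI_JOINTS_PRINTED_COL_MEANS = np.array([24.21, 22.78, 32.09, 30.01, 34.74, 23.62, 21.39])
GEI_PRINTED_COL_MEANS = np.array([21.98, 23.45, 36.24, 38.68, 35.21, 24.75, 21.06])

# same-view means across the seven views, per probe condition
SAME_VIEW_COVARIATE_MEANS = {
    "GSI-Lines": {"NM": 73.0, "BG": 67.2, "CL": 52.8},
    "GSI-Joints": {"NM": 74.8, "BG": 68.9, "CL": 54.1},
    "GEI": {"NM": 96.9, "BG": 85.4, "CL": 71.2},
}
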