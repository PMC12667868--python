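"""Fixed reference inputs for the report-aggregation arithmetic tests.

Per-image object-detection counts (Hit / Miss / Partial) over a
40-image validation set, and per-image pixel-contingency counts
(# margin pixels, total pixel error) with their expected one-decimal
fold-error column.  These are inputs to the aggregators, not values the
package computes.
"""

# (sample_id, hit, miss, partial)
DETECTION_COUNTS = [
    ("5dpg_01", 19, 0, 0),
    ("5dpg_02", 12, 1, 0),
    ("5dpg_03", 14, 1, 1),
    ("5dpg_04", 17, 2, 0),
    ("5dpg_05", 12, 1, 1),
    ("5dpg_06", 15, 0, 0),
    ("5dpg_07", 11, 0, 3),
    ("5dpg_08", 12, 2, 2),
    ("5dpg_09", 14, 0, 0),
    ("5dpg_10", 17, 0, 1),
    ("5dpg_11", 13, 1, 1),
    ("5dpg_12", 13, 1, 1),
    ("5dpg_13", 13, 0, 0),
    ("5dpg_14", 11, 0, 4),
    ("5dpg_15", 17, 0, 2),
    ("5dpg_16", 16, 0, 0),
    ("4dpg_01", 16, 0, 1),
    ("4dpg_02", 11, 3, 1),
    ("4dpg_03", 13, 1, 0),
    ("4dpg_04", 14, 2, 0),
    ("4dpg_05", 14, 2, 2),
    ("4dpg_06", 17, 0, 2),
    ("4dpg_07", 11, 1, 0),
    ("4dpg_08", 14, 0, 3),
    ("4dpg_09", 14, 2, 0),
    ("4dpg_10", 11, 3, 1),
    ("4dpg_11", 12, 0, 2),
    ("4dpg_12", 15, 3, 1),
    ("3dpg_01", 10, 1, 0),
    ("3dpg_02", 10, 0, 0),
    ("3dpg_03", 11, 0, 1),
    ("3dpg_04", 9, 1, 4),
    ("3dpg_05", 11, 1, 0),
    ("3dpg_06", 9, 1, 2),
    ("3dpg_07", 9, 3, 3),
    ("3dpg_08", 7, 0, 1),
    ("3dpg_09", 8, 0, 0),
    ("3dpg_10", 8, 2, 3),
    ("3dpg_11", 11, 0, 2),
    ("3dpg_12", 13, 1, 1),
]

# (image_id, iou_pct, annotated_pixels, margin_pixels, total_pixel_error,
#  fold_error_1dp)
CONTINGENCY_ROWS = [
    ("B0", 88.4, 133939, 39217, 15557, 0.4),
    ("B1", 83.2, 95465, 29195, 16062, 0.6),
    ("B2", 83.2, 213280, 61797, 35914, 0.6),
    ("C0", 92.8, 112785, 32396, 8135, 0.3),
    ("C1", 92.9, 278316, 77111, 19768, 0.3),
    ("C2", 93.2, 132810, 37805, 9093, 0.2),
    ("C3", 88.8, 194832, 56892, 21838, 0.4),
    ("C4", 89.0, 276002, 82750, 30268, 0.4),
    ("S0", 90.2, 18678, 6577, 1837, 0.3),
    ("S1", 95.1, 7395, 1196, 360, 0.3),
    ("S2", 66.4, 21077, 6577, 7087, 1.1),
    ("S3", 62.4, 3962, 1196, 1489, 1.2),
    ("S4", 63.5, 12809, 4198, 4669, 1.1),
]
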