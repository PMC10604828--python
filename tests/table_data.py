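"""Published per-model confusion counts and printed percentages used as
golden values by the metric tests (binary micro-averaging, so TN = TP and
FN = FP in every column)."""

MODELS = (
    "Xception",
    "VGG16",
    "VGG19",
    "MobileNet",
    "MobileNetV2",
    "MobileNetV3Small",
    "MobileNetV3Large",
    "NASNetMobile",
    "DenseNet201",
)

# Aquila-optimized models
AO_TP = (5351, 5357, 5341, 5356, 5333, 5329, 5299, 5311, 5359)
AO_FP = (25, 35, 47, 20, 27, 47, 81, 65, 17)
AO_ACCURACY = (99.53, 99.35, 99.13, 99.63, 99.50, 99.13, 98.49, 98.79, 99.68)
AO_YOUDEN = (99.07, 98.70, 98.26, 99.26, 98.99, 98.25, 96.99, 97.58, 99.37)
AO_AUC = (99.95, 99.98, 99.29, 99.95, 99.86, 99.90, 99.82, 99.20, 99.99)

# Gorilla-Troops-optimized models
GTO_TP = (5356, 5320, 5258, 5342, 5200, 5232, 5230, 4779, 5334)
GTO_FP = (20, 48, 130, 22, 176, 148, 130, 617, 30)
GTO_ACCURACY = (99.63, 99.11, 97.59, 99.59, 96.73, 97.25, 97.57, 88.57, 99.44)
GTO_YOUDEN = (99.26, 98.21, 95.17, 99.18, 93.45, 94.50, 95.15, 77.13, 98.88)
GTO_AUC = (99.99, 99.97, 99.71, 99.99, 99.24, 99.64, 99.57, 94.99, 99.99)

# Published suite-wide averages
AO_MEAN_ACCURACY = 99.25
AO_MEAN_YOUDEN = 98.50
AO_MEAN_AUC = 99.77
GTO_MEAN_ACCURACY = 97.27
GTO_MEAN_YOUDEN = 94.55
GTO_MEAN_AUC = 99.23
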