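"""Frozen per-species reference parameters for the eight Malagasy species.

Individual-level means +/- SD with [min, max], transcribed from the
published species-wise summary: absolute cephalic size CS in micrometres,
every other entry a dimensionless ratio (trait / CS unless the key names a
different denominator).  Cdep is an absolute depth in micrometres and, like
PSTI, is recorded only for the taxa carrying the character.
"""

# per species: {key: (mean, sd, min, max)}
REFERENCE_PARAMS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "angulatus": {
        "CS": (691.0, 28.49, 630.0, 727.0),
        "CL/CWb": (1.259, 0.03, 1.218, 1.327),
        "PoOC/CL": (0.370, 0.01, 0.355, 0.386),
        "FRS/CS": (0.325, 0.01, 0.310, 0.343),
        "SL/CS": (0.815, 0.02, 0.757, 0.866),
        "EL/CS": (0.281, 0.01, 0.262, 0.317),
        "MW/CS": (0.673, 0.02, 0.643, 0.699),
        "PEW/CS": (0.407, 0.03, 0.344, 0.451),
        "PPW/CS": (0.486, 0.03, 0.427, 0.546),
        "SPBA/CS": (0.323, 0.02, 0.265, 0.354),
        "SPTI/CS": (0.332, 0.02, 0.251, 0.375),
        "ML/CS": (1.390, 0.03, 1.302, 1.444),
        "PEL/CS": (0.522, 0.02, 0.482, 0.557),
        "NOL/CS": (0.383, 0.02, 0.317, 0.418),
        "PPL/CS": (0.285, 0.01, 0.250, 0.319),
        "SPST/CS": (0.271, 0.02, 0.223, 0.304),
        "MPST/CS": (0.434, 0.01, 0.385, 0.456),
        "PEH/CS": (0.401, 0.02, 0.362, 0.446),
        "NOH/CS": (0.231, 0.01, 0.203, 0.251),
        "PPH/CS": (0.357, 0.01, 0.333, 0.380),
        "PSTI/CS": (0.689, 0.03, 0.584, 0.736),
    },
    "bidentatus": {
        "CS": (510.0, 27.4, 419.0, 569.0),
        "CL/CWb": (1.277, 0.03, 1.204, 1.352),
        "PoOC/CL": (0.416, 0.01, 0.398, 0.440),
        "FRS/CS": (0.399, 0.01, 0.376, 0.419),
        "SL/CS": (0.665, 0.02, 0.634, 0.708),
        "EL/CS": (0.264, 0.02, 0.233, 0.311),
        "MW/CS": (0.647, 0.01, 0.621, 0.678),
        "PEW/CS": (0.391, 0.02, 0.330, 0.426),
        "PPW/CS": (0.456, 0.01, 0.425, 0.491),
        "SPBA/CS": (0.346, 0.02, 0.303, 0.372),
        "SPTI/CS": (0.335, 0.02, 0.303, 0.367),
        "ML/CS": (1.338, 0.02, 1.280, 1.379),
        "PEL/CS": (0.571, 0.02, 0.537, 0.605),
        "NOL/CS": (0.321, 0.02, 0.277, 0.362),
        "PPL/CS": (0.280, 0.01, 0.255, 0.305),
        "SPST/CS": (0.264, 0.02, 0.220, 0.335),
        "MPST/CS": (0.428, 0.01, 0.391, 0.458),
        "PEH/CS": (0.387, 0.01, 0.366, 0.424),
        "NOH/CS": (0.219, 0.01, 0.189, 0.249),
        "PPH/CS": (0.355, 0.01, 0.327, 0.381),
    },
    "clypeatus": {
        "CS": (898.0, 34.0, 850.0, 946.0),
        "CL/CWb": (1.076, 0.01, 1.057, 1.105),
        "PoOC/CL": (0.434, 0.01, 0.423, 0.444),
        "FRS/CS": (0.310, 0.01, 0.300, 0.328),
        "SL/CS": (0.758, 0.03, 0.736, 0.835),
        "EL/CS": (0.210, 0.01, 0.193, 0.225),
        "MW/CS": (0.699, 0.02, 0.671, 0.732),
        "PEW/CS": (0.460, 0.03, 0.428, 0.512),
        "PPW/CS": (0.493, 0.02, 0.472, 0.521),
        "SPBA/CS": (0.349, 0.02, 0.326, 0.386),
        "SPTI/CS": (0.463, 0.02, 0.438, 0.489),
        "ML/CS": (1.307, 0.03, 1.257, 1.347),
        "PEL/CS": (0.589, 0.02, 0.558, 0.642),
        "NOL/CS": (0.317, 0.02, 0.290, 0.336),
        "PPL/CS": (0.259, 0.01, 0.231, 0.278),
        "SPST/CS": (0.361, 0.01, 0.335, 0.385),
        "MPST/CS": (0.389, 0.01, 0.353, 0.405),
        "PEH/CS": (0.389, 0.02, 0.348, 0.434),
        "NOH/CS": (0.243, 0.02, 0.226, 0.278),
        "PPH/CS": (0.332, 0.02, 0.275, 0.365),
        "PSTI/CS": (0.773, 0.02, 0.733, 0.801),
        "Cdep": (19.245, 2.80, 15.385, 23.077),
    },
    "devius": {
        "CS": (593.0, 18.7, 562.0, 620.0),
        "CL/CWb": (1.188, 0.02, 1.147, 1.259),
        "PoOC/CL": (0.394, 0.01, 0.375, 0.408),
        "FRS/CS": (0.415, 0.01, 0.400, 0.428),
        "SL/CS": (0.632, 0.01, 0.616, 0.661),
        "EL/CS": (0.263, 0.01, 0.248, 0.279),
        "MW/CS": (0.687, 0.01, 0.658, 0.712),
        "PEW/CS": (0.447, 0.01, 0.422, 0.481),
        "PPW/CS": (0.499, 0.02, 0.464, 0.534),
        "SPBA/CS": (0.371, 0.01, 0.347, 0.402),
        "SPTI/CS": (0.430, 0.01, 0.401, 0.460),
        "ML/CS": (1.256, 0.02, 1.223, 1.285),
        "PEL/CS": (0.543, 0.01, 0.513, 0.565),
        "NOL/CS": (0.304, 0.01, 0.281, 0.332),
        "PPL/CS": (0.298, 0.01, 0.276, 0.313),
        "SPST/CS": (0.340, 0.01, 0.304, 0.356),
        "MPST/CS": (0.395, 0.01, 0.378, 0.416),
        "PEH/CS": (0.419, 0.01, 0.395, 0.439),
        "NOH/CS": (0.244, 0.01, 0.227, 0.268),
        "PPH/CS": (0.370, 0.01, 0.350, 0.384),
    },
    "exiguus": {
        "CS": (586.0, 26.2, 528.0, 644.0),
        "CL/CWb": (1.213, 0.02, 1.174, 1.255),
        "PoOC/CL": (0.408, 0.01, 0.391, 0.428),
        "FRS/CS": (0.413, 0.01, 0.397, 0.431),
        "SL/CS": (0.656, 0.01, 0.615, 0.683),
        "EL/CS": (0.249, 0.01, 0.228, 0.266),
        "MW/CS": (0.684, 0.01, 0.656, 0.728),
        "PEW/CS": (0.437, 0.02, 0.387, 0.480),
        "PPW/CS": (0.516, 0.01, 0.481, 0.548),
        "SPBA/CS": (0.390, 0.02, 0.352, 0.454),
        "SPTI/CS": (0.436, 0.02, 0.377, 0.493),
        "ML/CS": (1.298, 0.02, 1.214, 1.342),
        "PEL/CS": (0.578, 0.02, 0.496, 0.623),
        "NOL/CS": (0.327, 0.01, 0.279, 0.353),
        "PPL/CS": (0.302, 0.01, 0.274, 0.330),
        "SPST/CS": (0.382, 0.02, 0.317, 0.430),
        "MPST/CS": (0.420, 0.01, 0.394, 0.445),
        "PEH/CS": (0.436, 0.01, 0.406, 0.469),
        "NOH/CS": (0.261, 0.01, 0.236, 0.292),
        "PPH/CS": (0.388, 0.01, 0.356, 0.411),
    },
    "fragilis": {
        "CS": (539.0, 31.4, 469.0, 614.0),
        "CL/CWb": (1.229, 0.02, 1.189, 1.278),
        "PoOC/CL": (0.404, 0.01, 0.389, 0.421),
        "FRS/CS": (0.409, 0.01, 0.379, 0.430),
        "SL/CS": (0.659, 0.02, 0.615, 0.694),
        "EL/CS": (0.260, 0.01, 0.239, 0.276),
        "MW/CS": (0.664, 0.01, 0.627, 0.688),
        "PEW/CS": (0.407, 0.02, 0.363, 0.460),
        "PPW/CS": (0.470, 0.02, 0.429, 0.507),
        "SPBA/CS": (0.369, 0.02, 0.327, 0.405),
        "SPTI/CS": (0.377, 0.02, 0.337, 0.424),
        "ML/CS": (1.308, 0.03, 1.231, 1.345),
        "PEL/CS": (0.567, 0.03, 0.519, 0.717),
        "NOL/CS": (0.317, 0.01, 0.292, 0.347),
        "PPL/CS": (0.286, 0.01, 0.265, 0.308),
        "SPST/CS": (0.310, 0.02, 0.257, 0.356),
        "MPST/CS": (0.420, 0.02, 0.384, 0.449),
        "PEH/CS": (0.406, 0.01, 0.378, 0.431),
        "NOH/CS": (0.235, 0.01, 0.210, 0.257),
        "PPH/CS": (0.364, 0.01, 0.329, 0.394),
    },
    "gracilis": {
        "CS": (620.0, 38.0, 508.0, 699.0),
        "CL/CWb": (1.199, 0.02, 1.154, 1.246),
        "PoOC/CL": (0.387, 0.01, 0.372, 0.406),
        "FRS/CS": (0.413, 0.01, 0.390, 0.436),
        "SL/CS": (0.647, 0.01, 0.622, 0.685),
        "EL/CS": (0.252, 0.01, 0.228, 0.274),
        "MW/CS": (0.693, 0.02, 0.659, 0.726),
        "PEW/CS": (0.454, 0.02, 0.390, 0.487),
        "PPW/CS": (0.500, 0.02, 0.453, 0.539),
        "SPBA/CS": (0.393, 0.02, 0.350, 0.433),
        "SPTI/CS": (0.489, 0.02, 0.448, 0.536),
        "ML/CS": (1.267, 0.02, 1.201, 1.301),
        "PEL/CS": (0.574, 0.02, 0.541, 0.639),
        "NOL/CS": (0.324, 0.01, 0.278, 0.347),
        "PPL/CS": (0.301, 0.01, 0.280, 0.332),
        "SPST/CS": (0.399, 0.03, 0.301, 0.446),
        "MPST/CS": (0.407, 0.01, 0.374, 0.425),
        "PEH/CS": (0.435, 0.01, 0.417, 0.459),
        "NOH/CS": (0.272, 0.01, 0.250, 0.292),
        "PPH/CS": (0.385, 0.01, 0.354, 0.410),
    },
    "hirtellus": {
        "CS": (592.0, 26.5, 525.0, 641.0),
        "CL/CWb": (1.187, 0.02, 1.142, 1.242),
        "PoOC/CL": (0.387, 0.01, 0.366, 0.404),
        "FRS/CS": (0.412, 0.01, 0.385, 0.427),
        "SL/CS": (0.667, 0.02, 0.611, 0.705),
        "EL/CS": (0.272, 0.01, 0.249, 0.289),
        "MW/CS": (0.692, 0.01, 0.664, 0.730),
        "PEW/CS": (0.460, 0.02, 0.409, 0.522),
        "PPW/CS": (0.525, 0.02, 0.475, 0.585),
        "SPBA/CS": (0.389, 0.02, 0.345, 0.427),
        "SPTI/CS": (0.460, 0.02, 0.418, 0.504),
        "ML/CS": (1.315, 0.02, 1.261, 1.379),
        "PEL/CS": (0.585, 0.02, 0.487, 0.645),
        "NOL/CS": (0.324, 0.02, 0.299, 0.407),
        "PPL/CS": (0.315, 0.01, 0.266, 0.333),
        "SPST/CS": (0.375, 0.01, 0.332, 0.416),
        "MPST/CS": (0.425, 0.02, 0.391, 0.463),
        "PEH/CS": (0.436, 0.01, 0.402, 0.479),
        "NOH/CS": (0.273, 0.01, 0.240, 0.310),
        "PPH/CS": (0.400, 0.01, 0.378, 0.438),
    },
}

#: Published per-species specimen counts from the confirmation matrix.
REFERENCE_CLASS_SIZES: dict[str, int] = {
    "angulatus": 33,
    "bidentatus": 60,
    "clypeatus": 12,
    "devius": 27,
    "exiguus": 84,
    "fragilis": 42,
    "gracilis": 44,
    "hirtellus": 75,
}
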