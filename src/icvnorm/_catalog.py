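"""Default regional catalog and its calibration constants.

The catalog covers the 51 hemisphere-averaged FreeSurfer measures commonly
reported in aging studies: 17 subcortical and 34 cortical regions.  Each
entry carries normative per-gender summary statistics (mean and SD in mm^3)
for a cognitively normal population of 75-year-olds, which the synthetic
generator uses as calibration targets.  The calibration is approximate by
design: it reproduces the target cell means exactly and the SDs roughly.
"""

from __future__ import annotations

#: ICV (mm^3) per gender in the normative elderly population: (mean, sd)
NORMATIVE_ICV = {"F": (1440320.0, 121240.0), "M": (1638419.0, 140237.0)}

#: normative sample sizes behind the summary statistics
NORMATIVE_N = {"F": 193, "M": 213}

# name: (female mean, female sd, male mean, male sd, tissue)
# tissue classes: "gm" gray matter, "wm" white matter, "csf" ventricles/CSF
SUBCORTICAL = {
    "lateral_ventricle": (16108, 7352, 22240, 10083, "csf"),
    "inferior_lateral_ventricle": (691, 400, 1032, 522, "csf"),
    "cerebellum_wm": (13060, 1846, 13603, 2055, "wm"),
    "cerebellum_cortex": (45579, 4262, 49411, 5116, "gm"),
    "thalamus": (5711, 562, 6216, 579, "gm"),
    "caudate": (3210, 485, 3506, 612, "gm"),
    "putamen": (4275, 592, 4587, 590, "gm"),
    "pallidum": (1418, 165, 1545, 166, "gm"),
    "third_ventricle": (1628, 511, 2113, 671, "csf"),
    "fourth_ventricle": (1647, 585, 1922, 633, "csf"),
    "brainstem": (19169, 2051, 20931, 2401, "gm"),
    "hippocampus": (3405, 379, 3515, 384, "gm"),
    "amygdala": (1241, 167, 1401, 181, "gm"),
    "csf": (1348, 416, 1609, 463, "csf"),
    "accumbens": (439, 69, 471, 70, "gm"),
    "ventral_dc": (3415, 315, 3738, 366, "gm"),
    "corpus_callosum": (2638, 363, 2779, 411, "wm"),
}

CORTICAL = {
    "bankssts": (2034, 291, 2202, 331, "gm"),
    "caudal_anterior_cingulate": (1792, 298, 1890, 352, "gm"),
    "caudal_middle_frontal": (5167, 870, 5536, 922, "gm"),
    "cuneus": (2386, 334, 2674, 397, "gm"),
    "entorhinal": (1757, 268, 2016, 306, "gm"),
    "fusiform": (8077, 1090, 8842, 1116, "gm"),
    "inferior_parietal": (11619, 1522, 12587, 1591, "gm"),
    "inferior_temporal": (9039, 1177, 10024, 1343, "gm"),
    "isthmus_cingulate": (2123, 299, 2388, 319, "gm"),
    "lateral_occipital": (9638, 1201, 10551, 1288, "gm"),
    "lateral_orbitofrontal": (6265, 636, 6711, 628, "gm"),
    "lingual": (5169, 705, 5633, 738, "gm"),
    "medial_orbitofrontal": (4300, 513, 4667, 504, "gm"),
    "middle_temporal": (9508, 1130, 10275, 1236, "gm"),
    "parahippocampal": (1794, 258, 1906, 288, "gm"),
    "paracentral": (2944, 405, 3160, 478, "gm"),
    "pars_opercularis": (3581, 523, 3757, 543, "gm"),
    "pars_orbitalis": (2011, 248, 2123, 264, "gm"),
    "pars_triangularis": (3059, 414, 3265, 476, "gm"),
    "pericalcarine": (1691, 293, 1890, 298, "gm"),
    "postcentral": (7895, 927, 8425, 1018, "gm"),
    "posterior_cingulate": (2710, 351, 2949, 385, "gm"),
    "precentral": (10859, 1156, 11563, 1302, "gm"),
    "precuneus": (7859, 964, 8643, 946, "gm"),
    "rostral_anterior_cingulate": (2108, 356, 2348, 334, "gm"),
    "rostral_middle_frontal": (12684, 1532, 13992, 1622, "gm"),
    "superior_frontal": (17886, 1934, 19609, 2087, "gm"),
    "superior_parietal": (11161, 1366, 11991, 1427, "gm"),
    "superior_temporal": (9630, 1085, 10290, 1129, "gm"),
    "supramarginal": (8746, 1093, 9616, 1094, "gm"),
    "frontal_pole": (819, 144, 861, 136, "gm"),
    "temporal_pole": (2267, 312, 2348, 302, "gm"),
    "transverse_temporal": (854, 168, 888, 169, "gm"),
    "insula": (6219, 648, 6842, 686, "gm"),
}

SUBCORTICAL_REGIONS = tuple(SUBCORTICAL)
CORTICAL_REGIONS = tuple(CORTICAL)
ALL_REGIONS = SUBCORTICAL_REGIONS + CORTICAL_REGIONS

#: default Bonferroni families: each report table is its own family
DEFAULT_FAMILIES = {
    "subcortical": SUBCORTICAL_REGIONS,
    "cortical": CORTICAL_REGIONS,
}


def tissue_class(region: str) -> str:
    if region in SUBCORTICAL:
        return SUBCORTICAL[region][4]
    if region in CORTICAL:
        return CORTICAL[region][4]
    raise KeyError(f"unknown catalog region: {region!r}")
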