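"""Fixed registry of the 108 per-lesion features.

The order is stable and defines CSV column order everywhere: the nine texture
families first (59 features), then the 49 first-order SUV indices.  Names are
``<family prefix>_<index>``; family prefixes:

========  =================================================  =====
prefix    parent matrix                                      count
========  =================================================  =====
glcm      grey-level co-occurrence matrix                        7
rlm       voxel-alignment (run-length) matrix                   11
ngtdm     neighbourhood intensity-difference matrix              5
szm       intensity size-zone matrix                            11
nglcm     normalized co-occurrence matrix                        6
ts        texture spectrum                                       2
tfc       texture feature coding                                 4
tfcc      texture-feature-coding co-occurrence matrix            8
ngldm     neighbourhood grey-level dependence matrix             5
suv       first-order SUV indices                               49
========  =================================================  =====

SUV-bearing indices are in g/ml (SUL indices in SUL units), volume in ml,
surface area in mm^2; texture indices are dimensionless.
"""

from __future__ import annotations

FAMILIES: list[tuple[str, list[str]]] = [
    ("glcm", ["second_angular_moment", "contrast", "entropy", "homogeneity",
              "dissimilarity", "inverse_difference_moment", "correlation"]),
    ("rlm", ["short_run_emphasis", "long_run_emphasis", "intensity_variability",
             "run_length_variability", "run_percentage",
             "low_intensity_run_emphasis", "high_intensity_run_emphasis",
             "low_intensity_short_run_emphasis", "high_intensity_short_run_emphasis",
             "low_intensity_long_run_emphasis", "high_intensity_long_run_emphasis"]),
    ("ngtdm", ["coarseness", "contrast", "busyness", "complexity", "strength"]),
    ("szm", ["short_zone_emphasis", "large_zone_emphasis", "intensity_variability",
             "size_zone_variability", "zone_percentage",
             "low_intensity_zone_emphasis", "high_intensity_zone_emphasis",
             "low_intensity_short_zone_emphasis", "high_intensity_short_zone_emphasis",
             "low_intensity_large_zone_emphasis", "high_intensity_large_zone_emphasis"]),
    ("nglcm", ["second_angular_moment", "contrast", "entropy", "homogeneity",
               "inverse_difference_moment", "dissimilarity"]),
    ("ts", ["max_spectrum", "black_white_symmetry"]),
    ("tfc", ["coarseness", "homogeneity", "mean_convergence", "variance"]),
    ("tfcc", ["second_angular_moment", "contrast", "entropy", "homogeneity",
              "intensity", "inverse_difference_moment", "correlation", "variance"]),
    ("ngldm", ["small_number_emphasis", "large_number_emphasis",
               "number_nonuniformity", "second_moment", "entropy"]),
    ("suv", ["min", "max", "mean", "variance", "sd", "skewness", "kurtosis",
             "skewness_bias_corrected", "kurtosis_bias_corrected",
             "tlg", "volume_ml", "entropy", "sul_peak", "surface_area_mm2",
             "asphericity_1", "asphericity_2", "asphericity_3",
             "surface_mean_suv_1", "surface_total_suv_1", "surface_suv_entropy_1",
             "surface_suv_variance_1", "surface_suv_sd_1", "surface_suv_nsr_1",
             "surface_mean_suv_2", "surface_total_suv_2", "surface_suv_entropy_2",
             "surface_suv_variance_2", "surface_suv_sd_2", "surface_suv_nsr_2",
             "surface_mean_suv_3", "surface_total_suv_3", "surface_suv_entropy_3",
             "surface_suv_variance_3", "surface_suv_sd_3", "surface_suv_nsr_3",
             "surface_mean_suv_4", "surface_total_suv_4", "surface_suv_entropy_4",
             "surface_suv_variance_4", "surface_suv_sd_4", "surface_suv_nsr_4",
             "suv_mean_prod_asphericity", "suv_max_prod_asphericity",
             "entropy_prod_asphericity", "sul_peak_prod_asphericity",
             "suv_mean_prod_surface_area", "suv_max_prod_surface_area",
             "entropy_prod_surface_area", "sul_peak_prod_surface_area"]),
]

#: Family -> feature count (sums to 108: 59 texture + 49 SUV).
FAMILY_COUNTS: dict[str, int] = {fam: len(names) for fam, names in FAMILIES}

N_FEATURES = sum(FAMILY_COUNTS.values())
N_TEXTURE = N_FEATURES - FAMILY_COUNTS["suv"]


def feature_names() -> list[str]:
    """The 108 registry names in fixed order."""
    return [f"{fam}_{name}" for fam, names in FAMILIES for name in names]


def registry_dict() -> dict:
    """JSON-serializable registry dump (for CLI auditing)."""
    return {
        "n_features": N_FEATURES,
        "families": [
            {"prefix": fam, "count": len(names),
             "features": [f"{fam}_{n}" for n in names]}
            for fam, names in FAMILIES
        ],
    }
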