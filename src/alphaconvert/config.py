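"""Cohort and pipeline configuration.

The default :class:`CohortConfig` encodes the study conditions the synthetic
cohorts emulate: three groups (healthy older adults, stable amnestic MCI,
and amnestic MCI that converted to Alzheimer's disease within two years),
medial-temporal volumetry and cognitive scores per group, group-graded
retained-trial counts for the EEG analysis, and event-related
desynchronization (ERD) depths that are strongest in controls and weakest in
converters. A single latent factor links posterior-cingulate alpha ERD
during encoding to associative recognition memory within the stable-MCI
group, with a configurable target squared correlation (default 0.48).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
import yaml

from .exceptions import ConfigError

GROUPS = ("HO", "aMCI-s", "aMCI-c")
BANDS = ("alpha", "beta")
TASKS = ("encoding", "memory")
MTL_REGIONS = ("hippocampus", "amygdala")
HEMISPHERES = ("L", "R")
COGNITION_SCORES = ("mmse", "immediate_recall", "delayed_recall")

#: toy source-space cortical parcels used by the label volume
CORTICAL_REGIONS = (
    "l_pcc",
    "r_pcc",
    "l_cuneus_precuneus",
    "l_acc",
    "r_parahippocampal",
    "l_inferior_parietal",
    "cortex_other",
)

DEFAULT_GROUP_SIZES = {"HO": 26, "aMCI-s": 18, "aMCI-c": 16}

# mean, SD in mm^3 per group x (region, hemisphere)
DEFAULT_VOLUME_PARAMS = {
    "HO": {
        ("hippocampus", "L"): (3220.8, 303.4),
        ("hippocampus", "R"): (3231.9, 355.5),
        ("amygdala", "L"): (1437.9, 97.4),
        ("amygdala", "R"): (1459.2, 164.6),
    },
    "aMCI-s": {
        ("hippocampus", "L"): (2837.0, 563.5),
        ("hippocampus", "R"): (2981.4, 481.0),
        ("amygdala", "L"): (1280.3, 281.6),
        ("amygdala", "R"): (1395.8, 229.6),
    },
    "aMCI-c": {
        ("hippocampus", "L"): (2556.6, 483.7),
        ("hippocampus", "R"): (2701.2, 333.5),
        ("amygdala", "L"): (1169.9, 178.9),
        ("amygdala", "R"): (1196.4, 155.7),
    },
}

DEFAULT_COGNITION_PARAMS = {
    "HO": {"mmse": (28.4, 1.3), "immediate_recall": (14.3, 3.1), "delayed_recall": (13.2, 2.9)},
    "aMCI-s": {"mmse": (26.8, 2.1), "immediate_recall": (10.5, 2.3), "delayed_recall": (8.3, 3.4)},
    "aMCI-c": {"mmse": (26.4, 2.7), "immediate_recall": (8.9, 2.7), "delayed_recall": (4.5, 2.9)},
}

DEFAULT_AGE_PARAMS = {"HO": (66.7, 4.9), "aMCI-s": (68.4, 7.1), "aMCI-c": (69.7, 6.5)}
DEFAULT_EDUCATION_PARAMS = {"HO": (7.3, 4.4), "aMCI-s": (7.3, 5.1), "aMCI-c": (7.7, 6.3)}
DEFAULT_FEMALE_COUNTS = {"HO": 13, "aMCI-s": 13, "aMCI-c": 9}

# ICV is not tabulated in the source cohort; typical adult values are used.
DEFAULT_ICV_PARAMS = {g: (1.45e6, 1.4e5) for g in GROUPS}

# mean, SD of trials retained for the EEG analysis after condition matching
DEFAULT_TRIAL_COUNT_PARAMS = {"HO": (55.7, 12.8), "aMCI-s": (46.1, 15.0), "aMCI-c": (38.8, 12.5)}

# congruency benefit in d' units; converters show none
DEFAULT_CONGRUENCY_BENEFIT = {"HO": 0.35, "aMCI-s": 0.35, "aMCI-c": 0.0}
DEFAULT_OMISSION_RATE = {"HO": 0.001, "aMCI-s": 0.027, "aMCI-c": 0.01}
DEFAULT_ENCODING_ACCURACY = {"HO": 0.93, "aMCI-s": 0.91, "aMCI-c": 0.90}
DEFAULT_PRIMING_ACCURACY = {"HO": 0.95, "aMCI-s": 0.93, "aMCI-c": 0.92}
DEFAULT_MEMORY_RT_MEAN = {"HO": 900.0, "aMCI-s": 950.0, "aMCI-c": 1000.0}


def _erd(ho, s, c, sd=9.0):
    return {"HO": (ho, sd), "aMCI-s": (s, sd), "aMCI-c": (c, sd)}


# ERD depth (% change vs baseline; negative = desynchronization) per
# (band, task) -> region -> group.  "cortex_other" is the diffuse background
# level of every unlisted parcel.  Depths follow the configured ordering
# HO <= aMCI-s <= aMCI-c (controls desynchronize most, converters least).
DEFAULT_ERD_EFFECT = {
    ("alpha", "encoding"): {
        "cortex_other": _erd(-26.0, -20.0, -18.5, sd=4.0),
        "l_pcc": _erd(-44.0, -38.0, -19.0),
        "r_pcc": _erd(-40.0, -35.0, -21.0),
        "l_inferior_parietal": _erd(-38.0, -33.0, -21.0),
    },
    ("alpha", "memory"): {
        "cortex_other": _erd(-24.0, -19.0, -17.5, sd=4.0),
        "l_cuneus_precuneus": _erd(-43.0, -37.0, -17.0),
        "r_pcc": _erd(-36.0, -31.0, -18.0),
    },
    ("beta", "encoding"): {
        "cortex_other": _erd(-18.0, -14.5, -13.0, sd=4.0),
        "l_acc": _erd(-31.0, -27.0, -13.0),
    },
    ("beta", "memory"): {
        "cortex_other": _erd(-16.0, -12.5, -11.5, sd=4.0),
        "r_parahippocampal": _erd(-26.0, -23.0, -11.0),
    },
}


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``behavior_link`` is the target squared correlation between left-PCC
    alpha ERD during encoding and associative d' within the aMCI-s group;
    the link is absent from the other two groups.
    """

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    volume_params: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_VOLUME_PARAMS))
    cognition_params: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_COGNITION_PARAMS))
    age_params: dict = field(default_factory=lambda: dict(DEFAULT_AGE_PARAMS))
    education_params: dict = field(default_factory=lambda: dict(DEFAULT_EDUCATION_PARAMS))
    icv_params: dict = field(default_factory=lambda: dict(DEFAULT_ICV_PARAMS))
    female_counts: dict = field(default_factory=lambda: dict(DEFAULT_FEMALE_COUNTS))
    trial_count_params: dict = field(default_factory=lambda: dict(DEFAULT_TRIAL_COUNT_PARAMS))
    congruency_benefit: dict = field(default_factory=lambda: dict(DEFAULT_CONGRUENCY_BENEFIT))
    omission_rate: dict = field(default_factory=lambda: dict(DEFAULT_OMISSION_RATE))
    encoding_accuracy: dict = field(default_factory=lambda: dict(DEFAULT_ENCODING_ACCURACY))
    priming_accuracy: dict = field(default_factory=lambda: dict(DEFAULT_PRIMING_ACCURACY))
    memory_rt_mean: dict = field(default_factory=lambda: dict(DEFAULT_MEMORY_RT_MEAN))
    erd_effect: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_ERD_EFFECT))
    erd_voxel_noise_sd: float = 7.0
    behavior_link: float = 0.48
    n_targets_per_condition: int = 18
    n_lures_per_condition: int = 18
    sampling_rate: float = 250.0
    seed: int = 0
    include_maps: bool = True

    def groups(self) -> tuple:
        return tuple(self.group_sizes)

    def validate(self) -> "CohortConfig":
        """Check invariants; raise :class:`ConfigError` naming the offending field."""
        if not self.group_sizes:
            raise ConfigError("group_sizes: no groups declared")
        for g, n in self.group_sizes.items():
            if not isinstance(n, int) or n <= 0:
                raise ConfigError(f"group_sizes[{g}]: size must be a positive integer, got {n!r}")
        for g in self.group_sizes:
            for name, params in (
                ("volume_params", self.volume_params),
                ("cognition_params", self.cognition_params),
                ("age_params", self.age_params),
                ("trial_count_params", self.trial_count_params),
            ):
                if g not in params:
                    raise ConfigError(f"{name}: missing group {g!r}")
        for g, per_region in self.volume_params.items():
            for key, (mean, sd) in per_region.items():
                if sd <= 0:
                    raise ConfigError(f"volume_params[{g}][{key}]: SD must be > 0, got {sd}")
                if mean <= 0:
                    raise ConfigError(f"volume_params[{g}][{key}]: mean volume must be > 0")
        for g, per_score in self.cognition_params.items():
            for score, (_, sd) in per_score.items():
                if sd <= 0:
                    raise ConfigError(f"cognition_params[{g}][{score}]: SD must be > 0, got {sd}")
        for g, (_, sd) in self.trial_count_params.items():
            if sd <= 0:
                raise ConfigError(f"trial_count_params[{g}]: SD must be > 0, got {sd}")
        for key, per_region in self.erd_effect.items():
            for region, per_group in per_region.items():
                for g, (_, sd) in per_group.items():
                    if sd < 0:
                        raise ConfigError(f"erd_effect[{key}][{region}][{g}]: SD must be >= 0")
        if not 0.0 <= self.behavior_link < 1.0:
            raise ConfigError(f"behavior_link: must be in [0, 1), got {self.behavior_link}")
        if self.sampling_rate <= 0:
            raise ConfigError(f"sampling_rate: must be > 0, got {self.sampling_rate}")
        if min(self.n_targets_per_condition, self.n_lures_per_condition) < 2:
            raise ConfigError("n_targets_per_condition/n_lures_per_condition: need >= 2")
        return self


@dataclass
class RunConfig:
    """Configuration of one full pipeline run (all stages, one master seed)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    # spectral stage demo: epochs are synthesized for this many subjects
    spectral_demo_subjects: int = 3
    spectral_demo_channels: int = 8
    cluster_threshold_p: float = 0.05
    cluster_n_perm: int = 200
    pls_n_perm: int = 200
    pls_n_boot: int = 200
    cv_rounds: int = 34
    predict_n_perm: int = 200
    rw_n_boot: int = 500
    entry_p: float = 0.05
    removal_p: float = 0.10
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.cohort.validate()
        for name in ("cluster_n_perm", "pls_n_perm", "cv_rounds", "predict_n_perm"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name}: must be >= 1")
        if not 0 < self.cluster_threshold_p < 1:
            raise ConfigError("cluster_threshold_p: must be in (0, 1)")
        return self


def load_run_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file.

    Top-level keys map to RunConfig fields; the ``cohort`` key holds
    CohortConfig overrides (tuple-keyed tables such as ``erd_effect`` are
    only overridable programmatically).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = raw.pop("cohort", {}) or {}
    cohort = CohortConfig(**cohort_raw)
    cfg = RunConfig(cohort=cohort, **raw)
    return cfg.validate()
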