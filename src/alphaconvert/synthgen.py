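"""Synthetic cohort generation.

Generates complete cohorts — subject records, trial tables, and per-subject
3D source-grid ERD maps — with the statistical structure the downstream
analysis assumes:

* group sizes, demographics, medial-temporal volumes and cognitive scores
  drawn from the configured per-group means/SDs;
* recognition behavior driven by a latent memory ability ``m`` through an
  equal-variance signal-detection model (hit rate Phi(m/2), false-alarm
  rate Phi(-m/2)), with the group distribution of ``m`` moment-calibrated so
  that the number of trials retained after condition matching reproduces the
  configured per-group mean and SD;
* ERD depths per cortical parcel that are deepest (most negative) in
  controls and shallowest in converters;
* a planted association between left-PCC alpha ERD during encoding and
  associative d', present only in the stable-MCI group, via a latent factor
  shared between ability and the PCC ERD depth.

Sensor-space epochs are synthesized on demand (:func:`make_epochs`,
:func:`plant_oscillation`) as 1/f background noise plus band-limited
oscillations whose event-window amplitude is attenuated relative to
baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import BANDS, TASKS, CohortConfig
from .exceptions import BoundsError, ConfigError, LabelError

CONDITIONS = ("SCF", "SIF")

#: 59-channel scalp montage (extended 10-20 labels)
CHANNELS_59 = (
    "Fp1 Fpz Fp2 AF3 AF4 F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO7 PO3 POz PO4 PO8 O1 Oz O2 Iz"
).split()

# epoch spans (s, relative to face onset); generous pre-stimulus intervals so
# the wavelet support of the analyzed frequencies clears the baseline windows
EPOCH_SPANS = {"encoding": (-2.8, 1.1), "memory": (-1.3, 1.1)}


# ---------------------------------------------------------------------------
# containers


@dataclass
class EpochArray:
    """Per-subject EEG trials: channels x samples x trials."""

    data: np.ndarray  # (n_channels, n_samples, n_trials), microvolts
    channels: Sequence[str]
    sampling_rate: float
    onset_index: int
    trial_conditions: np.ndarray
    task: str

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to event onset."""
        idx = np.arange(self.n_samples) - self.onset_index
        return idx * 1000.0 / self.sampling_rate


@dataclass
class Atlas:
    """Toy anatomical parcellation on a regular voxel grid."""

    label_volume: np.ndarray  # int ids, 0 = outside
    names: dict  # id -> region name
    affine: np.ndarray  # voxel -> mm
    voxel_size: float = 5.0

    def id_of(self, name: str) -> int:
        for i, n in self.names.items():
            if n == name:
                return i
        raise LabelError(name)

    def mask(self, name: str) -> np.ndarray:
        return self.label_volume == self.id_of(name)


@dataclass
class SourceMapSet:
    """Stack of per-subject source-grid ERD maps sharing one atlas."""

    values: np.ndarray  # (n_subjects, nx, ny, nz), percent change
    subject_ids: np.ndarray
    groups: np.ndarray
    atlas: Atlas
    band: str
    task: str

    @property
    def grid_shape(self) -> tuple:
        return self.values.shape[1:]

    def region_mean(self, region: str) -> np.ndarray:
        """Per-subject mean ERD over one labeled parcel."""
        m = self.atlas.mask(region)
        return self.values[:, m].mean(axis=1)


@dataclass
class Cohort:
    config: CohortConfig
    subjects: pd.DataFrame
    trials: pd.DataFrame
    maps: dict = field(default_factory=dict)  # (band, task) -> SourceMapSet
    atlas: Atlas | None = None
    regional_erd: pd.DataFrame | None = None  # per-subject parcel-level ERD


# ---------------------------------------------------------------------------
# ability calibration

def _phi2(a: float, rho: float) -> float:
    """P(Z1 <= a, Z2 <= a) for standard bivariate normal with correlation rho."""
    cov = [[1.0, rho], [rho, 1.0]]
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([a, a]))


@lru_cache(maxsize=128)
def ability_params(mean_trials: float, sd_trials: float, benefit: float, n_per_cond: int) -> tuple:
    """Solve for the N(mu, sigma) ability distribution reproducing retained-trial moments.

    Retained trials after condition matching equal ``T * Phi((m - benefit/2)/2)``
    with ``T = 4 * n_per_cond`` (the weaker, incongruent condition binds).
    Using E[Phi(c + dU)] = Phi(a) with a = c/sqrt(1+d^2) and
    Var[Phi(c + dU)] = Phi2(a, a; d^2/(1+d^2)) - Phi(a)^2, the two moment
    equations reduce to a closed form for ``a`` and a 1-D root for the
    variance, so the calibration is deterministic and exact in expectation.
    """
    T = 4.0 * n_per_cond
    p_target = mean_trials / T
    if not 0.0 < p_target < 1.0:
        raise ConfigError(f"trial_count_params: mean {mean_trials} outside (0, {T})")
    a = stats.norm.ppf(p_target)
    v_target = (sd_trials / T) ** 2
    v_max = p_target * (1.0 - p_target)
    if v_target >= v_max:
        raise ConfigError(
            f"trial_count_params: SD {sd_trials} unreachable (max {T * math.sqrt(v_max):.1f})"
        )

    def f(rho):
        return _phi2(a, rho) - p_target**2 - v_target

    rho = None
    lo, hi = 1e-9, 1.0 - 1e-9
    from scipy.optimize import brentq

    rho = brentq(f, lo, hi, xtol=1e-12)
    d = math.sqrt(rho / (1.0 - rho))
    c = a * math.sqrt(1.0 + d * d)
    mu = 2.0 * c + benefit / 2.0
    sigma = 2.0 * d
    return mu, sigma


# ---------------------------------------------------------------------------
# atlas


def build_atlas(grid_shape=(12, 14, 12), voxel_size: float = 5.0) -> Atlas:
    """Toy cortical parcellation: box-shaped parcels on a small 5-mm grid."""
    vol = np.zeros(grid_shape, dtype=np.int16)
    names = {1: "cortex_other"}
    vol[:] = 1
    boxes = {
        "l_pcc": (slice(2, 5), slice(3, 6), slice(5, 8)),
        "r_pcc": (slice(7, 10), slice(3, 6), slice(5, 8)),
        "l_cuneus_precuneus": (slice(2, 5), slice(0, 3), slice(6, 9)),
        "l_acc": (slice(2, 5), slice(9, 12), slice(5, 8)),
        "r_parahippocampal": (slice(7, 10), slice(5, 8), slice(1, 4)),
        "l_inferior_parietal": (slice(0, 3), slice(2, 5), slice(8, 11)),
    }
    for i, (name, box) in enumerate(boxes.items(), start=2):
        vol[box] = i
        names[i] = name
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = -voxel_size * (np.asarray(grid_shape) - 1) / 2.0
    return Atlas(label_volume=vol, names=names, affine=affine, voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# cohort generation


def _smooth_noise(rng, shape, sd, sigma=0.8):
    """Mildly smoothed Gaussian voxel noise with marginal SD ``sd``."""
    white = rng.standard_normal(shape)
    if sigma <= 0:
        return sd * white
    sm = ndimage.gaussian_filter(white, sigma=sigma, mode="nearest")
    impulse = np.zeros((9, 9, 9))
    impulse[4, 4, 4] = 1.0
    norm = math.sqrt(float((ndimage.gaussian_filter(impulse, sigma=sigma) ** 2).sum()))
    return sd * sm / norm


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate one synthetic cohort; reproducible given config and seed."""
    config = (config or CohortConfig()).validate()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)

    n_t, n_l = config.n_targets_per_condition, config.n_lures_per_condition
    subj_rows = []
    trial_rows = []
    regional_rows = []
    erd_regions = {
        key: sorted(per_region) for key, per_region in config.erd_effect.items()
    }

    for group, n in config.group_sizes.items():
        a_mu, a_sd = config.age_params[group]
        e_mu, e_sd = config.education_params[group]
        benefit = config.congruency_benefit.get(group, 0.0)
        tmu, tsd = config.trial_count_params[group]
        m_mu, m_sigma = ability_params(tmu, tsd, benefit, n_t)
        # floor: at least 2 correct trials per condition must be achievable
        m_floor = benefit / 2.0 + 2.0 * stats.norm.ppf(1.0 / (2.0 * n_t))

        n_female = min(config.female_counts.get(group, n // 2), n)
        for k in range(n):
            sid = f"{group}-{k + 1:02d}"
            age = rng.normal(a_mu, a_sd)
            edu = max(0.0, rng.normal(e_mu, e_sd))
            sex = "F" if k < n_female else "M"
            vols = {}
            for (region, hemi), (vmu, vsd) in config.volume_params[group].items():
                lo = (1.0 - vmu) / vsd
                vols[(region, hemi)] = vmu + vsd * stats.truncnorm.rvs(lo, np.inf, random_state=rng)
            icv_mu, icv_sd = config.icv_params[group]
            icv = rng.normal(icv_mu, icv_sd)
            icv = max(icv, 2.0 * sum(vols.values()))
            cog = {s: rng.normal(*config.cognition_params[group][s]) for s in config.cognition_params[group]}

            # latent ability (truncated normal) and its standardized form
            lo = (m_floor - m_mu) / m_sigma
            m = m_mu + m_sigma * stats.truncnorm.rvs(lo, np.inf, random_state=rng)
            u = (m - m_mu) / m_sigma

            # parcel-level ERD per band/task; PCC alpha encoding shares the
            # ability factor within aMCI-s only (negative: deeper ERD <-> better memory)
            reg_vals = {}
            for (band, task), per_region in config.erd_effect.items():
                for region in erd_regions[(band, task)]:
                    mu_e, sd_e = per_region[region][group]
                    eps = rng.standard_normal()
                    if (
                        group == "aMCI-s"
                        and band == "alpha"
                        and task == "encoding"
                        and region == "l_pcc"
                        and config.behavior_link > 0
                    ):
                        rho = math.sqrt(config.behavior_link)
                        z = -rho * u + math.sqrt(1.0 - config.behavior_link) * eps
                    else:
                        z = eps
                    reg_vals[f"{band}_{task}_{region}"] = mu_e + sd_e * z

            subj_rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age": age,
                    "sex": sex,
                    "education": edu,
                    "icv": icv,
                    **{f"{r}_{h}": v for (r, h), v in vols.items()},
                    **cog,
                }
            )
            regional_rows.append({"subject_id": sid, "group": group, **reg_vals})
            trial_rows.extend(
                _subject_trials(rng, config, sid, group, m, benefit, n_t, n_l)
            )

    subjects = pd.DataFrame(subj_rows)
    trials = pd.DataFrame(trial_rows)
    regional = pd.DataFrame(regional_rows)

    cohort = Cohort(config=config, subjects=subjects, trials=trials, regional_erd=regional)
    if config.include_maps:
        atlas = build_atlas()
        cohort.atlas = atlas
        for (band, task), per_region in config.erd_effect.items():
            vals = np.empty((len(subjects),) + atlas.label_volume.shape)
            background = regional[f"{band}_{task}_cortex_other"].to_numpy()
            vals[:] = background[:, None, None, None]
            for region in erd_regions[(band, task)]:
                if region == "cortex_other":
                    continue
                mask = atlas.mask(region)
                vals[:, mask] = regional[f"{band}_{task}_{region}"].to_numpy()[:, None]
            for i in range(len(subjects)):
                vals[i] += _smooth_noise(rng, atlas.label_volume.shape, config.erd_voxel_noise_sd)
            cohort.maps[(band, task)] = SourceMapSet(
                values=vals,
                subject_ids=subjects["subject_id"].to_numpy(),
                groups=subjects["group"].to_numpy(),
                atlas=atlas,
                band=band,
                task=task,
            )
    return cohort


def _subject_trials(rng, config, sid, group, m, benefit, n_t, n_l):
    """Trial table rows for one subject across the three task phases."""
    rows = []
    rt_mu = config.memory_rt_mean[group] + rng.normal(0.0, 80.0)

    def rt():
        return max(200.0, rng.normal(rt_mu, 150.0))

    # --- memory (recognition) phase: counts are deterministic given ability
    miss_rows = []
    for cond in CONDITIONS:
        m_c = m + (benefit / 2.0 if cond == "SCF" else -benefit / 2.0)
        hit_rate = stats.norm.cdf(m_c / 2.0)
        hits = int(round(n_t * hit_rate))
        fas = int(round(n_l * stats.norm.cdf(-m_c / 2.0)))
        for j in range(n_t):
            correct = j < hits
            row = {
                "subject_id": sid,
                "phase": "memory",
                "condition": cond,
                "is_target": True,
                "correct": correct,
                "responded": True,
                "rt": rt(),
            }
            rows.append(row)
            if not correct:
                miss_rows.append(row)
        for j in range(n_l):
            correct = j >= fas
            rows.append(
                {
                    "subject_id": sid,
                    "phase": "memory",
                    "condition": cond,
                    "is_target": False,
                    "correct": correct,
                    "responded": True,
                    "rt": rt(),
                }
            )
    # omissions are carved from misses only, so hit/FA counts (hence d') are untouched
    n_mem = 2 * (n_t + n_l)
    n_om = min(rng.binomial(n_mem, config.omission_rate.get(group, 0.0)), len(miss_rows))
    for row in rng.permutation(len(miss_rows))[:n_om]:
        miss_rows[row]["responded"] = False
        miss_rows[row]["rt"] = np.nan

    # --- encoding and priming phases (descriptive only)
    for phase, acc in (
        ("encoding", config.encoding_accuracy[group]),
        ("priming", config.priming_accuracy[group]),
    ):
        for cond in CONDITIONS:
            for _ in range(n_t + n_l):
                fast = 150.0 if (phase == "priming" and cond == "SCF") else 0.0
                rows.append(
                    {
                        "subject_id": sid,
                        "phase": phase,
                        "condition": cond,
                        "is_target": False,
                        "correct": bool(rng.random() < acc),
                        "responded": True,
                        "rt": max(200.0, rng.normal(rt_mu - 200.0 - fast, 120.0)),
                    }
                )
    return rows


# ---------------------------------------------------------------------------
# epochs


def _pink_noise(rng, n_channels, n_samples, n_trials, sfreq, sd):
    """1/f-amplitude-shaped Gaussian noise, marginal SD ``sd``."""
    if sd == 0:
        return np.zeros((n_channels, n_samples, n_trials))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(freqs[nz])
    shape[0] = 0.0
    spec = rng.standard_normal((n_channels, freqs.size, n_trials)) + 1j * rng.standard_normal(
        (n_channels, freqs.size, n_trials)
    )
    x = np.fft.irfft(spec * shape[None, :, None], n=n_samples, axis=1)
    x *= sd / x.std()
    return x


def make_epochs(
    task: str = "encoding",
    n_trials: int = 40,
    channels: Sequence[str] | None = None,
    sampling_rate: float = 250.0,
    noise_sd: float = 1.0,
    conditions: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> EpochArray:
    """Synthesize background epochs for one subject and task.

    Epochs span the per-task interval required to cover the baseline windows
    of the time-frequency analysis (encoding from -2800 ms, memory from
    -1300 ms, both through +1100 ms).
    """
    if task not in EPOCH_SPANS:
        raise ConfigError(f"task: expected one of {sorted(EPOCH_SPANS)}, got {task!r}")
    rng = rng or np.random.default_rng(0)
    channels = list(channels) if channels is not None else list(CHANNELS_59)
    tmin, tmax = EPOCH_SPANS[task]
    n_samples = int(round((tmax - tmin) * sampling_rate)) + 1
    onset_index = int(round(-tmin * sampling_rate))
    data = _pink_noise(rng, len(channels), n_samples, n_trials, sampling_rate, noise_sd)
    if conditions is None:
        conditions = np.asarray([CONDITIONS[i % 2] for i in range(n_trials)])
    return EpochArray(
        data=data,
        channels=channels,
        sampling_rate=sampling_rate,
        onset_index=onset_index,
        trial_conditions=np.asarray(conditions),
        task=task,
    )


def plant_oscillation(
    epoch: EpochArray,
    band_center: float,
    event_attenuation: float,
    event_window: tuple,
    amplitude: float = 1.0,
    rng: np.random.Generator | None = None,
) -> EpochArray:
    """Add a band-limited oscillation with attenuated event-window amplitude.

    The oscillation has amplitude ``amplitude`` throughout the epoch and
    ``amplitude * (1 - event_attenuation)`` inside ``event_window`` (ms
    relative to onset), so the planted event/baseline power ratio is
    ``(1 - event_attenuation)**2`` — attenuation ``1 - 1/sqrt(2)`` yields an
    ERD of exactly -50% for the planted component.
    """
    if not 0.0 <= event_attenuation <= 1.0:
        raise ConfigError(f"event_attenuation: must be in [0, 1], got {event_attenuation}")
    times = epoch.times_ms()
    w0, w1 = event_window
    if w0 >= w1:
        raise BoundsError(f"event_window: start {w0} must precede end {w1}")
    if w0 < times[0] or w1 > times[-1]:
        raise BoundsError(
            f"event_window {event_window} outside epoch span [{times[0]:.0f}, {times[-1]:.0f}] ms"
        )
    rng = rng or np.random.default_rng(0)
    t = times / 1000.0
    env = np.where((times >= w0) & (times <= w1), 1.0 - event_attenuation, 1.0)
    data = epoch.data.copy()
    n_ch, _, n_tr = data.shape
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_ch, n_tr))
    osc = amplitude * env[None, :, None] * np.sin(
        2.0 * np.pi * band_center * t[None, :, None] + phases[:, None, :]
    )
    data += osc
    return replace(epoch, data=data)


def plant_source_effect(mapset: SourceMapSet, region_label: str, group_deltas: dict) -> SourceMapSet:
    """Add group-specific ERD offsets inside one labeled parcel only."""
    mask = mapset.atlas.mask(region_label)  # raises LabelError when unknown
    values = mapset.values.copy()
    for g, delta in group_deltas.items():
        sel = mapset.groups == g
        if np.any(sel) and delta:
            sub = values[sel]
            sub[:, mask] += delta
            values[sel] = sub
    return replace(mapset, values=values)
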