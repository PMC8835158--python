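"""Synthetic resting-EEG with known ground truth.

Real resting recordings carry two kinds of structure the analysis stages
are meant to recover: a *temporal* alternation between a few quasi-stable
scalp topographies (microstates, 60-120 ms lifetimes) and a *spatial*
synchronization profile per frequency band.  This module plants both:

* a semi-Markov class sequence (gamma-distributed lifetimes around
  per-class means, class-to-class transition matrix with zero diagonal)
  modulating four prototype topographies with a band-limited oscillatory
  carrier, buried in spatially correlated sensor noise at a chosen SNR;
* optional narrow-band components whose share of a common source versus
  independent per-channel sources sets the band's expected omega;
* a mode-mixture generator in which each channel carries one of
  ``n_modes`` independent band-limited sources, so the planted omega is
  (for balanced equal-weight partitions) the number of modes;
* two-group cohorts in which named effects (class occurrence and duration
  multipliers, per-band synchronization increments) are applied to the
  second group, together with a symptom score linear in the per-subject
  planted effect strength.

Everything is driven by ``numpy`` SeedSequence spawning, so a cohort is
bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .microstate import canonical_templates, spatial_correlation, CLASS_NAMES
from .montage import ChannelMontage, default_montage, generic_montage
from .preprocess import Recording

__all__ = [
    "BandComponent",
    "MicrostateGenParams",
    "SyncGenParams",
    "CohortSpec",
    "CohortSubject",
    "Cohort",
    "make_prototype_maps",
    "sample_state_sequence",
    "synthesize_recording",
    "synthesize_synchronized",
    "make_cohort",
    "DEFAULT_EFFECTS",
]


# ---------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class BandComponent:
    """A narrow-band process with a controllable common-mode share.

    Each channel receives sqrt(common_fraction) of one shared source plus
    sqrt(1 - common_fraction) of its own independent source, both
    band-limited to ``band_hz``; raising ``common_fraction`` lowers the
    band's omega.  ``power_ratio`` is the component's channel-mean power
    relative to the microstate signal power.
    """

    name: str
    band_hz: tuple[float, float]
    power_ratio: float = 0.4
    common_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.common_fraction <= 1:
            raise ValueError("common_fraction must lie in [0, 1]")
        if self.power_ratio < 0:
            raise ValueError("power_ratio must be nonnegative")


def _default_band_components() -> tuple[BandComponent, ...]:
    # beta-2 / gamma processes whose synchronization the cohort spec can shift
    return (
        BandComponent("beta2", (20.0, 30.0)),
        BandComponent("gamma", (30.0, 45.0)),
    )


@dataclass(frozen=True)
class MicrostateGenParams:
    """Generator settings for one microstate-structured recording.

    ``snr`` is the ratio of microstate-signal power to total noise power;
    ``numpy.inf`` disables noise and 0 disables the signal.  Segment
    lifetimes are gamma distributed (shape ``gamma_shape``) around the
    per-class means.  If ``transition_matrix`` is omitted it is built from
    ``occurrence_rate_hz`` (probability of entering a class proportional
    to its rate) or uniformly.
    """

    n_classes: int = 4
    mean_duration_ms: tuple[float, ...] | float = 80.0
    occurrence_rate_hz: tuple[float, ...] | None = None
    transition_matrix: np.ndarray | None = None
    carrier_band_hz: tuple[float, float] = (8.0, 12.0)
    snr: float = 10.0
    amplitude_uv: float = 15.0
    gamma_shape: float = 4.0
    spatial_noise_mix: float = 0.6
    spatial_decay: float = 0.5
    band_components: tuple[BandComponent, ...] = field(
        default_factory=_default_band_components)
    seed: int = 0

    def durations_ms(self) -> np.ndarray:
        d = np.broadcast_to(np.asarray(self.mean_duration_ms, dtype=float),
                            (self.n_classes,)).copy()
        if np.any(d <= 0):
            raise ValueError("mean durations must be positive")
        return d

    def transitions(self) -> np.ndarray:
        if self.transition_matrix is not None:
            t = np.asarray(self.transition_matrix, dtype=float)
            _validate_transitions(t, self.n_classes)
            return t
        n = self.n_classes
        if self.occurrence_rate_hz is not None:
            w = np.broadcast_to(np.asarray(self.occurrence_rate_hz, dtype=float),
                                (n,)).copy()
            if np.any(w <= 0):
                raise ValueError("occurrence rates must be positive")
        else:
            w = np.ones(n)
        t = np.tile(w, (n, 1))
        np.fill_diagonal(t, 0.0)
        return t / t.sum(axis=1, keepdims=True)


def _validate_transitions(t: np.ndarray, n: int) -> None:
    if t.shape != (n, n):
        raise ValueError(f"transition matrix must be {n}x{n}")
    if np.any(np.abs(np.diag(t)) > 0):
        raise ValueError("transition matrix diagonal must be exactly zero")
    if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition matrix rows must be stochastic")


@dataclass(frozen=True)
class SyncGenParams:
    """Settings for the mode-mixture synchronization generator."""

    n_channels: int
    n_modes: int
    mode_weights: tuple[float, ...] | None = None
    band_hz: tuple[float, float] = (8.0, 12.0)
    duration_s: float = 60.0
    fs_hz: float = 250.0
    noise_power: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ValueError("n_modes must be at least 1")
        if self.n_modes > self.n_channels:
            raise ValueError("n_modes cannot exceed n_channels")
        if self.noise_power < 0:
            raise ValueError("noise_power must be nonnegative")

    def weights(self) -> np.ndarray:
        if self.mode_weights is None:
            return np.full(self.n_modes, 1.0 / self.n_modes)
        w = np.asarray(self.mode_weights, dtype=float)
        if w.shape != (self.n_modes,) or np.any(w < 0):
            raise ValueError("mode_weights must be nonnegative, one per mode")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mode_weights must sum to 1")
        return w


# ---------------------------------------------------------------------------
# primitive signal builders

def _bandlimited_noise(rng: np.random.Generator, n: int, fs_hz: float,
                       low_hz: float, high_hz: float,
                       n_series: int = 1) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [low, high] Hz, (n_series, n)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    band = (freqs >= low_hz) & (freqs <= high_hz)
    if not band.any():
        raise ValueError("band contains no resolvable frequencies")
    spec = np.zeros((n_series, freqs.size), dtype=complex)
    m = int(band.sum())
    spec[:, band] = rng.standard_normal((n_series, m)) + 1j * rng.standard_normal((n_series, m))
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _spatial_noise(rng: np.random.Generator, n: int, montage: ChannelMontage,
                   mix: float, decay: float) -> np.ndarray:
    """Unit-power sensor noise: white + spatially correlated parts, (n, K)."""
    k = montage.n_channels
    white = rng.standard_normal((n, k))
    if mix <= 0:
        return white
    d = np.linalg.norm(montage.positions[:, None, :] - montage.positions[None, :, :],
                       axis=-1)
    cov = np.exp(-d / decay)
    # tiny ridge keeps the Cholesky stable for near-duplicate positions
    chol = np.linalg.cholesky(cov + 1e-9 * np.eye(k))
    smooth = rng.standard_normal((n, k)) @ chol.T
    smooth /= smooth.std()
    out = np.sqrt(1.0 - mix) * white + np.sqrt(mix) * smooth
    return out / out.std()


# ---------------------------------------------------------------------------
# public generators

def make_prototype_maps(montage: ChannelMontage, seed: int,
                        jitter: float = 0.08) -> np.ndarray:
    """Four zero-mean unit-norm prototype maps in canonical A-D orientation.

    Canonical templates built from the electrode layout are perturbed by
    seeded Gaussian jitter so that different seeds give distinct but
    recognizable map sets.  Pairwise absolute spatial correlations are
    verified to stay below 0.8.
    """
    if montage.n_channels < 4:
        raise ValueError("montage must have at least 4 positioned channels")
    rng = np.random.default_rng(seed)
    maps = canonical_templates(montage)
    maps = maps + jitter * rng.standard_normal(maps.shape)
    maps = maps - maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    r = np.abs(spatial_correlation(maps, maps))
    np.fill_diagonal(r, 0.0)
    if r.max() >= 0.8:
        raise RuntimeError(
            f"prototype maps too similar (max |r| = {r.max():.3f}); lower jitter")
    return maps


def sample_state_sequence(params: MicrostateGenParams, duration_s: float,
                          fs_hz: float,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-sample class labels from the semi-Markov microstate model.

    Lifetimes are gamma draws (shape ``params.gamma_shape``, mean the
    per-class mean duration), rounded to at least one sample; successive
    classes follow the transition matrix, so adjacent segments always
    differ in class.
    """
    n = int(round(duration_s * fs_hz))
    if n < 1:
        raise ValueError("duration_s * fs_hz must be at least 1 sample")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    means_s = params.durations_ms() / 1000.0
    trans = params.transitions()
    shape = params.gamma_shape
    state = int(rng.integers(params.n_classes))
    labels = np.empty(n, dtype=int)
    pos = 0
    while pos < n:
        life_s = rng.gamma(shape, means_s[state] / shape)
        length = max(1, int(round(life_s * fs_hz)))
        end = min(n, pos + length)
        labels[pos:end] = state
        pos = end
        state = int(rng.choice(params.n_classes, p=trans[state]))
    return labels


def synthesize_recording(prototypes: np.ndarray, labels: np.ndarray,
                         params: MicrostateGenParams,
                         montage: ChannelMontage | None = None,
                         fs_hz: float = 250.0,
                         rng: np.random.Generator | None = None) -> Recording:
    """Render a label sequence into a multichannel recording.

    signal(t) = amplitude * carrier(t) * prototype[label(t)], with a
    band-limited unit-variance carrier, plus spatially structured noise at
    the requested SNR and any extra narrow-band components.
    """
    prototypes = np.asarray(prototypes, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= prototypes.shape[0]:
        raise ValueError("labels index outside the prototype set")
    if montage is None:
        montage = default_montage()
    if prototypes.shape[1] != montage.n_channels:
        raise ValueError("prototype channel count does not match montage")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = labels.size
    k = montage.n_channels

    carrier = _bandlimited_noise(rng, n, fs_hz, *params.carrier_band_hz)[0]
    amp = params.amplitude_uv if params.snr > 0 else 0.0
    data = amp * carrier[:, None] * prototypes[labels]
    # reference power is label-independent: unit-norm maps spread power 1/K
    p_signal = params.amplitude_uv ** 2 / k

    if np.isfinite(params.snr):
        noise = _spatial_noise(rng, n, montage, params.spatial_noise_mix,
                               params.spatial_decay)
        p_noise = p_signal / params.snr if params.snr > 0 else p_signal
        data = data + np.sqrt(p_noise) * noise

    for comp in params.band_components:
        lo, hi = comp.band_hz
        if hi >= fs_hz / 2:
            continue
        common = _bandlimited_noise(rng, n, fs_hz, lo, hi)[0]
        indep = _bandlimited_noise(rng, n, fs_hz, lo, hi, n_series=k).T
        mixd = (np.sqrt(comp.common_fraction) * common[:, None]
                + np.sqrt(1.0 - comp.common_fraction) * indep)
        data = data + np.sqrt(comp.power_ratio * p_signal) * mixd

    return Recording(data=data, fs_hz=fs_hz, montage=montage)


def synthesize_synchronized(params: SyncGenParams,
                            rng: np.random.Generator | None = None) -> Recording:
    """Recording whose in-band omega is controlled by the number of modes.

    Channels are partitioned round-robin over ``n_modes`` independent
    band-limited sources; a channel in mode m carries that source scaled
    by sqrt(n_modes * w_m).  With one mode all channels are identical
    copies (omega -> 1); with as many equally weighted modes as channels
    they are independent (omega -> n_channels).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs_hz))
    sources = _bandlimited_noise(rng, n, params.fs_hz, *params.band_hz,
                                 n_series=params.n_modes)
    w = params.weights()
    mode_of = np.arange(params.n_channels) % params.n_modes
    gains = np.sqrt(params.n_modes * w[mode_of])
    data = sources[mode_of].T * gains[None, :]
    if params.noise_power > 0:
        data = data + np.sqrt(params.noise_power) * rng.standard_normal(data.shape)
    return Recording(data=data, fs_hz=params.fs_hz,
                     montage=generic_montage(params.n_channels))


# ---------------------------------------------------------------------------
# cohorts

#: Named effects applied to the second group, emulating the direction of
#: the group contrast the analysis is meant to detect: more frequent class
#: B, shorter (hence less contributing) class C, and stronger beta-2/gamma
#: synchronization (lower omega).
DEFAULT_EFFECTS: dict = {
    "occurrence_multiplier": {"B": 1.3},
    "duration_multiplier": {"C": 1 / 1.3},
    "sync_increment": {"beta2": 0.25, "gamma": 0.25},
}


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort design.

    ``effect_map`` names the offsets applied to group-2 generator
    parameters; an empty map makes the groups exchangeable.  The symptom
    score is ``intercept(group) + symptom_coef * (subject effect strength)
    + N(0, symptom_sd)``, clipped into the screening windows of the two
    groups (controls 0-13, subclinical 14-27 on a BDI-II-like scale).
    """

    n_per_group: tuple[int, int] = (20, 20)
    #: 60 s of clean eyes-closed signal gives 30 two-second epochs, at
    #: least the global channel count, so the epoch-averaged 30x30
    #: cross-spectral matrix is full rank.
    duration_s: float = 60.0
    fs_hz: float = 250.0
    base_params: MicrostateGenParams = field(default_factory=MicrostateGenParams)
    effect_map: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    effect_strength_sd: float = 0.2
    symptom_coef: float = 8.0
    symptom_sd: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.symptom_sd < 0 or self.effect_strength_sd < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass(frozen=True)
class CohortSubject:
    subject_id: str
    group: str                     # "HC" or "ScD"
    score: float
    recording: Recording
    ground_truth: dict


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[CohortSubject, ...]
    prototypes: np.ndarray
    spec: CohortSpec

    def by_group(self, group: str) -> list[CohortSubject]:
        return [s for s in self.subjects if s.group == group]


def _apply_effects(params: MicrostateGenParams, effect_map: dict,
                   strength: float) -> MicrostateGenParams:
    """Scale group-2 generator parameters by the named effects.

    ``strength`` interpolates each multiplier m to 1 + strength*(m - 1)
    and each increment d to strength*d, giving per-subject effect-size
    variation around the planted mean.
    """
    def interp(m):
        return 1.0 + strength * (m - 1.0)

    durations = params.durations_ms()
    for cls, m in effect_map.get("duration_multiplier", {}).items():
        durations[CLASS_NAMES.index(cls)] *= interp(m)

    trans = params.transitions().copy()
    for cls, m in effect_map.get("occurrence_multiplier", {}).items():
        trans[:, CLASS_NAMES.index(cls)] *= interp(m)
    np.fill_diagonal(trans, 0.0)
    trans /= trans.sum(axis=1, keepdims=True)

    comps = []
    incs = effect_map.get("sync_increment", {})
    for comp in params.band_components:
        if comp.name in incs:
            cf = min(0.95, comp.common_fraction + strength * incs[comp.name])
            comp = replace(comp, common_fraction=cf)
        comps.append(comp)

    return replace(params, mean_duration_ms=tuple(durations),
                   transition_matrix=trans, band_components=tuple(comps))


def make_cohort(spec: CohortSpec,
                montage: ChannelMontage | None = None) -> Cohort:
    """Generate a two-group cohort with planted effects and ground truth.

    One prototype map set is shared by the whole cohort (as in a single
    study population); group-2 subjects get the effect map applied with a
    per-subject strength drawn around 1.  All randomness descends from
    ``spec.seed`` via SeedSequence spawning, so identical specs give
    bit-identical cohorts.
    """
    if montage is None:
        montage = default_montage()
    root = np.random.SeedSequence(spec.seed)
    proto_ss, *subject_ss = root.spawn(1 + sum(spec.n_per_group))
    prototypes = make_prototype_maps(montage,
                                     int(proto_ss.generate_state(1)[0] % 2**31))
    subjects = []
    idx = 0
    for g, (gname, n_g) in enumerate(zip(("HC", "ScD"), spec.n_per_group)):
        for _ in range(n_g):
            rng = np.random.default_rng(subject_ss[idx])
            if g == 1:
                strength = max(0.0, rng.normal(1.0, spec.effect_strength_sd))
                params = _apply_effects(spec.base_params, spec.effect_map, strength)
            else:
                strength = 0.0
                params = spec.base_params
            labels = sample_state_sequence(params, spec.duration_s, spec.fs_hz,
                                           rng=rng)
            rec = synthesize_recording(prototypes, labels, params,
                                       montage=montage, fs_hz=spec.fs_hz, rng=rng)
            base = 7.0 if g == 0 else 13.0
            score = base + spec.symptom_coef * strength + rng.normal(0.0, spec.symptom_sd)
            lo, hi = (0.0, 13.0) if g == 0 else (14.0, 27.0)
            score = float(np.clip(score, lo, hi))
            subjects.append(CohortSubject(
                subject_id=f"sub-{idx:03d}", group=gname, score=score,
                recording=rec,
                ground_truth={
                    "effect_strength": strength,
                    "mean_duration_ms": params.durations_ms(),
                    "transition_matrix": params.transitions(),
                    "labels": labels,
                }))
            idx += 1
    return Cohort(subjects=tuple(subjects), prototypes=prototypes, spec=spec)
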