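"""EEG microstate analysis: the temporal-dynamics stage.

Resting EEG decomposes into a small set of quasi-stable scalp potential
topographies ("microstates", conventionally four classes A-D) that persist
for 60-120 ms before switching.  The stage implemented here:

1. band-pass the clean epochs to 2-20 Hz,
2. compute global field power (GFP) and locate its peaks (moments of
   maximal topographic signal-to-noise),
3. cluster the peak topographies with the Topographic Atomize & Agglomerate
   Hierarchical Clustering (TAAHC) algorithm into four polarity-ignored
   prototype maps,
4. label every sample by back-fitting the prototypes,
5. summarise the label sequence as per-class mean duration, occurrence
   rate, time contribution, and the 4x4 transition-probability matrix,
   with global explained variance (GEV) as the goodness-of-fit index.

Polarity is ignored throughout: a topography and its negation belong to
the same microstate class, so all similarity is measured as the absolute
spatial (Pearson) correlation between average-referenced maps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin

from .montage import ChannelMontage
from .preprocess import EpochSet

__all__ = [
    "CLASS_NAMES",
    "canonical_templates",
    "compute_gfp",
    "find_gfp_peaks",
    "microstate_bandpass",
    "TAAHC",
    "taahc_cluster",
    "order_classes",
    "backfit",
    "compute_gev",
    "segment_stats",
    "transition_matrix",
    "MicrostateParams",
    "MicrostateModel",
    "fit_microstates",
    "fit_microstates_group",
]

CLASS_NAMES = ("A", "B", "C", "D")


# ---------------------------------------------------------------------------
# topography helpers

def _center(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=-1, keepdims=True)


def _unit(maps: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(maps, axis=-1, keepdims=True)
    norms = np.where(norms == 0, 1.0, norms)
    return maps / norms


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels between average-referenced maps.

    ``a``: (..., K), ``b``: (m, K) or (K,).  Returns the signed correlation;
    callers that ignore polarity take the absolute value.
    """
    a = _unit(_center(np.asarray(a, dtype=float)))
    b = _unit(_center(np.asarray(b, dtype=float)))
    return a @ b.T if b.ndim == 2 else a @ b


def canonical_templates(montage: ChannelMontage) -> np.ndarray:
    """Canonical A-D template maps for the montage, as a (4, K) array.

    Built from the electrode layout: A is a left-posterior to right-anterior
    gradient, B its mirror image, C an anterior-posterior gradient, D a
    fronto-central focal map.  Each row is zero-mean, unit-norm.
    """
    x, y = montage.positions[:, 0], montage.positions[:, 1]
    a = x + y
    b = -x + y
    c = y
    d = np.exp(-((x / 0.55) ** 2 + ((y - 0.25) / 0.55) ** 2))
    maps = np.vstack([a, b, c, d])
    return _unit(_center(maps))


# ---------------------------------------------------------------------------
# global field power

def compute_gfp(data: np.ndarray | EpochSet) -> np.ndarray:
    """Global field power: the spatial standard deviation of the topography.

    GFP(t) = sqrt( sum_i (v_i(t) - vbar(t))^2 / n ) over the n channels.
    Accepts an EpochSet (returns (n_epochs, n_times)) or an array whose last
    axis is channels.
    """
    arr = data.epochs if isinstance(data, EpochSet) else np.asarray(data, dtype=float)
    centered = arr - arr.mean(axis=-1, keepdims=True)
    return np.sqrt((centered ** 2).mean(axis=-1))


def find_gfp_peaks(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of a 1-D GFP series.

    Endpoints are never peaks; plateau samples are not peaks (both
    neighbours must be strictly lower).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("need a 1-D series of at least 3 samples")
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    return np.flatnonzero(interior) + 1


def microstate_bandpass(ep: EpochSet, low_hz: float = 2.0, high_hz: float = 20.0,
                        order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass of each epoch (default 2-20 Hz).

    An IIR filter is used here because epochs are short (2 s) relative to
    the impulse response a sharp FIR would need at a 2 Hz low edge.
    """
    nyq = ep.fs_hz / 2
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=ep.fs_hz,
                        output="sos")
    out = signal.sosfiltfilt(sos, ep.epochs, axis=1)
    return replace(ep, epochs=out)


# ---------------------------------------------------------------------------
# TAAHC clustering

class TAAHC(BaseEstimator, ClusterMixin):
    """Topographic Atomize & Agglomerate Hierarchical Clustering.

    Starts from singleton clusters and repeatedly *atomizes* the cluster
    that contributes least explained variance, reassigning each of its
    member maps to the surviving cluster whose prototype correlates best
    with it, until ``n_clusters`` remain.  With ``ignore_polarity`` (the
    convention for spontaneous EEG) similarity is the absolute spatial
    correlation and each prototype is the first principal direction of its
    member maps; otherwise the signed correlation and the normalized mean
    map are used.

    The procedure is deterministic: ties are broken toward the lowest
    cluster index.

    Parameters
    ----------
    n_clusters : int, default 4
        Number of prototype maps to retain.
    ignore_polarity : bool, default True
        Treat a map and its negation as identical.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_channels)
        Zero-mean, unit-norm prototype topographies.
    labels_ : ndarray of shape (n_samples,)
        Cluster index of each input map.
    gev_ : float
        Fraction of GFP-weighted map variance explained by the assignment.
    """

    def __init__(self, n_clusters: int = 4, ignore_polarity: bool = True):
        self.n_clusters = n_clusters
        self.ignore_polarity = ignore_polarity

    def fit(self, X, y=None, sample_weight=None):
        """Cluster map rows of X ((n_samples, n_channels), microvolts)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (maps x channels)")
        n, k = X.shape
        if n < self.n_clusters:
            raise ValueError(f"need at least {self.n_clusters} maps, got {n}")
        centered = _center(X)
        norms = np.linalg.norm(centered, axis=1)
        ok = norms > 0
        units = np.zeros_like(centered)
        units[ok] = centered[ok] / norms[ok, None]
        w = norms ** 2  # proportional to squared GFP of the map
        if sample_weight is not None:
            w = w * np.asarray(sample_weight, dtype=float)

        members: list[list[int] | None] = [[i] for i in range(n)]
        protos = units.copy()
        # contribution of a cluster to global explained variance
        contrib = w * 1.0  # singleton: |corr(u, u)| = 1
        alive = np.ones(n, dtype=bool)
        n_alive = n

        def _update_cluster(c: int) -> None:
            idx = members[c]
            U = units[idx]
            wc = w[idx]
            if self.ignore_polarity:
                scatter = (U * wc[:, None]).T @ U
                vals, vecs = np.linalg.eigh(scatter)
                p = vecs[:, -1]
            else:
                p = wc @ U
                nrm = np.linalg.norm(p)
                p = p / nrm if nrm > 0 else U[0]
            protos[c] = p
            r = U @ p
            if self.ignore_polarity:
                r = np.abs(r)
            contrib[c] = float(wc @ r ** 2)

        while n_alive > self.n_clusters:
            alive_idx = np.flatnonzero(alive)
            worst = alive_idx[np.argmin(contrib[alive_idx])]
            alive[worst] = False
            n_alive -= 1
            orphan = members[worst]
            members[worst] = None
            rest = np.flatnonzero(alive)
            sim = units[orphan] @ protos[rest].T
            if self.ignore_polarity:
                sim = np.abs(sim)
            best = rest[np.argmax(sim, axis=1)]
            touched = set()
            for m, c in zip(orphan, best):
                members[c].append(m)
                touched.add(c)
            for c in touched:
                _update_cluster(c)

        final = np.flatnonzero(alive)
        centers = _unit(_center(protos[final]))
        labels = np.empty(n, dtype=int)
        for new, c in enumerate(final):
            labels[members[c]] = new
        self.cluster_centers_ = centers
        self.labels_ = labels
        r = units @ centers.T
        if self.ignore_polarity:
            r = np.abs(r)
        assigned = r[np.arange(n), labels]
        total = float(w.sum())
        self.gev_ = float(w @ assigned ** 2 / total) if total > 0 else 0.0
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, y, **kwargs).labels_


def taahc_cluster(maps: np.ndarray, n_clusters: int = 4,
                  ignore_polarity: bool = True) -> np.ndarray:
    """Functional wrapper around :class:`TAAHC`; returns the prototypes."""
    return TAAHC(n_clusters=n_clusters,
                 ignore_polarity=ignore_polarity).fit(maps).cluster_centers_


def order_classes(prototypes: np.ndarray, templates: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Assign prototypes to canonical classes (A-D order of ``templates``).

    Solves the one-to-one assignment maximizing the total absolute spatial
    correlation.  Returns ``(ordered_prototypes, order)`` where
    ``ordered_prototypes[i]`` matches ``templates[i]`` and ``order`` is the
    permutation applied (``ordered = prototypes[order]``).  The sign of each
    returned prototype is flipped, if needed, to correlate positively with
    its template (cosmetic only; polarity is ignored downstream).
    """
    prototypes = np.asarray(prototypes, dtype=float)
    templates = np.asarray(templates, dtype=float)
    if prototypes.shape[0] != templates.shape[0]:
        raise ValueError("need as many prototypes as templates")
    r = spatial_correlation(templates, prototypes)  # (n_templates, n_protos)
    _, cols = linear_sum_assignment(-np.abs(r))
    ordered = prototypes[cols].copy()
    signs = np.sign(r[np.arange(len(cols)), cols])
    signs[signs == 0] = 1.0
    ordered *= signs[:, None]
    return _unit(_center(ordered)), cols


# ---------------------------------------------------------------------------
# backfitting and goodness of fit

def backfit(ep: EpochSet, prototypes: np.ndarray) -> np.ndarray:
    """Label every sample with its best-matching prototype.

    Each GFP peak takes the prototype of highest absolute spatial
    correlation; every other sample inherits the label of the nearest peak
    within its epoch (ties broken toward the earlier peak).  Epochs with no
    GFP peak fall back to per-sample assignment.

    Returns an ``(n_epochs, n_times)`` integer array.
    """
    protos = _unit(_center(np.asarray(prototypes, dtype=float)))
    labels = np.empty((ep.n_epochs, ep.n_times), dtype=int)
    for e in range(ep.n_epochs):
        data = ep.epochs[e]
        g = compute_gfp(data)
        peaks = find_gfp_peaks(g)
        if peaks.size == 0:
            r = np.abs(spatial_correlation(data, protos))
            labels[e] = np.argmax(r, axis=1)
            continue
        r = np.abs(spatial_correlation(data[peaks], protos))
        peak_lab = np.argmax(r, axis=1)
        t = np.arange(ep.n_times)
        # nearest peak; on an exact tie prefer the earlier peak
        pos = np.searchsorted(peaks, t)
        left = np.clip(pos - 1, 0, peaks.size - 1)
        right = np.clip(pos, 0, peaks.size - 1)
        choose_left = np.abs(t - peaks[left]) <= np.abs(peaks[right] - t)
        nearest = np.where(choose_left, left, right)
        labels[e] = peak_lab[nearest]
    return labels


def compute_gev(ep: EpochSet, labels: np.ndarray, prototypes: np.ndarray) -> float:
    """Global explained variance of a labelling.

    GEV = sum_t (GFP(t) * corr(v(t), p_label(t)))^2 / sum_t GFP(t)^2,
    pooled over epochs; in [0, 1].
    """
    protos = _unit(_center(np.asarray(prototypes, dtype=float)))
    labels = np.asarray(labels, dtype=int)
    data = ep.epochs.reshape(-1, ep.n_channels)
    lab = labels.reshape(-1)
    if lab.shape[0] != data.shape[0]:
        raise ValueError("labels must cover every sample")
    g = compute_gfp(data)
    r = spatial_correlation(data, protos)[np.arange(data.shape[0]), lab]
    denom = float((g ** 2).sum())
    if denom == 0:
        return 0.0
    return float(((g * r) ** 2).sum() / denom)


# ---------------------------------------------------------------------------
# label-sequence statistics

@dataclass(frozen=True)
class MicrostateParams:
    """Per-class temporal statistics of a microstate label sequence."""

    duration_ms: np.ndarray      # mean lifetime of complete segments
    occurrence_per_s: np.ndarray  # complete segments per second
    contribution_pct: np.ndarray  # percent of labelled samples
    transitions: np.ndarray       # row-stochastic, zero diagonal
    n_classes: int = 4


def _segments(row: np.ndarray):
    """Run-length encode one epoch's labels: (class, length, truncated) triples."""
    change = np.flatnonzero(np.diff(row)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [row.size]])
    classes = row[starts]
    lengths = ends - starts
    truncated = np.zeros(classes.size, dtype=bool)
    truncated[0] = True
    truncated[-1] = True
    return classes, lengths, truncated


def transition_matrix(labels: np.ndarray, n_classes: int = 4) -> np.ndarray:
    """Row-normalized counts of consecutive segment-class pairs.

    Transitions are counted between adjacent segments within an epoch
    (never across epoch boundaries); the diagonal is structurally zero.
    Rows for classes that never transition are all zero.
    """
    labels = np.atleast_2d(np.asarray(labels, dtype=int))
    counts = np.zeros((n_classes, n_classes))
    for row in labels:
        cls, _, _ = _segments(row)
        if cls.size > 1:
            np.add.at(counts, (cls[:-1], cls[1:]), 1)
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        probs = np.where(sums > 0, counts / np.where(sums == 0, 1, sums), 0.0)
    return probs


def segment_stats(labels: np.ndarray, fs_hz: float, n_classes: int = 4
                  ) -> MicrostateParams:
    """Duration, occurrence, contribution and transitions from labels.

    Segments truncated by an epoch boundary are excluded from the duration
    means and the occurrence counts (their true lifetime is unknown) but
    their samples still count toward contribution.
    """
    labels = np.atleast_2d(np.asarray(labels, dtype=int))
    n_total = labels.size
    total_s = n_total / fs_hz
    dur_sum = np.zeros(n_classes)
    dur_n = np.zeros(n_classes)
    samp = np.zeros(n_classes)
    for row in labels:
        cls, lengths, trunc = _segments(row)
        np.add.at(samp, cls, lengths)
        keep = ~trunc
        np.add.at(dur_sum, cls[keep], lengths[keep])
        np.add.at(dur_n, cls[keep], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        duration_ms = np.where(dur_n > 0, dur_sum / np.maximum(dur_n, 1), np.nan)
    duration_ms = duration_ms / fs_hz * 1000.0
    occurrence = dur_n / total_s
    contribution = samp / n_total * 100.0
    return MicrostateParams(duration_ms=duration_ms, occurrence_per_s=occurrence,
                            contribution_pct=contribution,
                            transitions=transition_matrix(labels, n_classes),
                            n_classes=n_classes)


# ---------------------------------------------------------------------------
# subject- and group-level convenience drivers

@dataclass(frozen=True)
class MicrostateModel:
    """Fitted microstate decomposition of one epoch set."""

    prototypes: np.ndarray   # (4, K), A-D order, zero-mean unit-norm
    labels: np.ndarray       # (n_epochs, n_times)
    gev: float
    params: MicrostateParams


def _peak_maps(ep: EpochSet, max_maps: int | None) -> np.ndarray:
    """GFP-peak topographies pooled over epochs, evenly subsampled to a cap."""
    maps = []
    for e in range(ep.n_epochs):
        g = compute_gfp(ep.epochs[e])
        pk = find_gfp_peaks(g)
        if pk.size:
            maps.append(ep.epochs[e][pk])
    if not maps:
        raise ValueError("no GFP peaks found")
    pooled = np.concatenate(maps, axis=0)
    if max_maps is not None and pooled.shape[0] > max_maps:
        idx = np.linspace(0, pooled.shape[0] - 1, max_maps).round().astype(int)
        pooled = pooled[np.unique(idx)]
    return pooled


def fit_microstates(ep: EpochSet, n_states: int = 4, band_hz=(2.0, 20.0),
                    templates: np.ndarray | None = None,
                    max_maps: int | None = 1000,
                    prototypes: np.ndarray | None = None) -> MicrostateModel:
    """Single-subject microstate pipeline.

    Filters to the microstate band, clusters GFP-peak maps with TAAHC
    (unless ``prototypes`` are supplied, e.g. group-level maps), orders the
    classes against the canonical templates, backfits, and summarises.
    """
    epf = microstate_bandpass(ep, *band_hz) if band_hz is not None else ep
    if templates is None:
        templates = canonical_templates(ep.montage)
    if prototypes is None:
        maps = _peak_maps(epf, max_maps)
        prototypes = taahc_cluster(maps, n_clusters=n_states)
    prototypes, _ = order_classes(prototypes, templates)
    labels = backfit(epf, prototypes)
    gev = compute_gev(epf, labels, prototypes)
    params = segment_stats(labels, epf.fs_hz, n_classes=n_states)
    return MicrostateModel(prototypes=prototypes, labels=labels, gev=gev,
                           params=params)


def fit_microstates_group(epoch_sets: list[EpochSet], n_states: int = 4,
                          band_hz=(2.0, 20.0), max_maps: int | None = 1000,
                          templates: np.ndarray | None = None
                          ) -> tuple[np.ndarray, list[MicrostateModel]]:
    """Two-stage group decomposition.

    Each subject's peak maps are clustered to ``n_states`` prototypes, the
    pooled subject prototypes are clustered again to group prototypes
    (weighting subjects equally), and every subject is backfitted with the
    group maps.  Returns ``(group_prototypes, per_subject_models)``.
    """
    if not epoch_sets:
        raise ValueError("empty cohort")
    if templates is None:
        templates = canonical_templates(epoch_sets[0].montage)
    subject_protos = []
    filtered = []
    for ep in epoch_sets:
        epf = microstate_bandpass(ep, *band_hz) if band_hz is not None else ep
        filtered.append(epf)
        maps = _peak_maps(epf, max_maps)
        subject_protos.append(taahc_cluster(maps, n_clusters=n_states))
    pooled = np.concatenate(subject_protos, axis=0)
    group_protos = taahc_cluster(pooled, n_clusters=n_states)
    group_protos, _ = order_classes(group_protos, templates)
    models = []
    for epf in filtered:
        labels = backfit(epf, group_protos)
        gev = compute_gev(epf, labels, group_protos)
        params = segment_stats(labels, epf.fs_hz, n_classes=n_states)
        models.append(MicrostateModel(prototypes=group_protos, labels=labels,
                                      gev=gev, params=params))
    return group_protos, models
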