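"""Subject-by-feature tables bridging the analysis stages.

One row per subject: microstate temporal parameters (per-class duration,
occurrence, contribution, the 12 ordered transition probabilities, GEV)
and omega spatial complexity (7 bands x 3 scopes), plus the group label
and symptom score.  The named feature sets used for classification select
the indicators that discriminate the groups: class-B occurrence, class-C
duration and contribution on the temporal side; regional theta/beta-2/
gamma and global beta-2/gamma omega on the spatial side.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .microstate import (CLASS_NAMES, MicrostateModel, fit_microstates_group)
from .omega import DEFAULT_BANDS, DEFAULT_SCOPES, omega_pipeline
from .preprocess import EpochSet, preprocess
from .synth import Cohort

__all__ = [
    "microstate_features",
    "omega_features",
    "subject_features",
    "cohort_features",
    "FEATURE_SETS",
]

#: Discriminative feature sets for classification.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "microstate": ("occ_B", "dur_C", "contrib_C"),
    "omega": ("omega_anterior_theta", "omega_posterior_theta",
              "omega_anterior_beta2", "omega_posterior_beta2",
              "omega_anterior_gamma", "omega_posterior_gamma",
              "omega_global_beta2", "omega_global_gamma"),
}
FEATURE_SETS["combined"] = FEATURE_SETS["microstate"] + FEATURE_SETS["omega"]


def microstate_features(model: MicrostateModel) -> dict[str, float]:
    """Flatten a fitted microstate model into named scalar features."""
    p = model.params
    out: dict[str, float] = {}
    for i, c in enumerate(CLASS_NAMES[: p.n_classes]):
        out[f"dur_{c}"] = float(p.duration_ms[i])
        out[f"occ_{c}"] = float(p.occurrence_per_s[i])
        out[f"contrib_{c}"] = float(p.contribution_pct[i])
    for i, a in enumerate(CLASS_NAMES[: p.n_classes]):
        for j, b in enumerate(CLASS_NAMES[: p.n_classes]):
            if i != j:
                out[f"t_{a}{b}"] = float(p.transitions[i, j])
    out["gev"] = float(model.gev)
    return out


def omega_features(ep: EpochSet, bands=DEFAULT_BANDS,
                   scopes=DEFAULT_SCOPES) -> dict[str, float]:
    """Omega per (band, scope) as named scalar features."""
    table = omega_pipeline(ep, bands=bands, scopes=scopes)
    return {f"omega_{r.scope}_{r.band}": float(r.omega)
            for r in table.itertuples()}


def subject_features(ep: EpochSet, model: MicrostateModel) -> dict[str, float]:
    return {**microstate_features(model), **omega_features(ep)}


def cohort_features(cohort: Cohort, max_maps: int | None = 300,
                    preprocess_kwargs: dict | None = None) -> pd.DataFrame:
    """Full analysis of a synthetic cohort into a feature table.

    Each recording is preprocessed, microstates are fitted with the
    two-stage (subject then group) clustering, and omega is computed on
    the broadband epochs.  Returns one row per subject with ``subject``,
    ``group``, ``score`` and all features.
    """
    kw = preprocess_kwargs or {}
    epochs = [preprocess(s.recording, **kw) for s in cohort.subjects]
    _, models = fit_microstates_group(epochs, max_maps=max_maps)
    rows = []
    for subj, ep, model in zip(cohort.subjects, epochs, models):
        rows.append({"subject": subj.subject_id, "group": subj.group,
                     "score": subj.score, **subject_features(ep, model)})
    return pd.DataFrame(rows)
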