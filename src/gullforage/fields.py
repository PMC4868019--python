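"""Gull presence on agricultural fields: derived columns and model set.

Presence/absence of lesser black-backed gulls per field observation is
modelled with binomial (Bernoulli) mixed models with field nested within
transect as random intercepts, ranked by AICc. Association models add
counts of earthworms, waders (lapwing + oystercatcher) and other gull
species (all gulls except the focal one) to the best-fitting
vegetation/time model.
"""

from __future__ import annotations

import pandas as pd

from .glmm import GlmmFit, fit_glmm, rank_models
from .synthetic import summarize_vegetation  # noqa: F401  (survey summary)

OTHER_GULLS = ["black_headed_gull", "common_gull", "herring_gull"]
WADERS = ["lapwing", "oystercatcher"]

#: candidate vegetation/time models (fixed parts; the nested random
#: intercepts are always included)
DEFAULT_MODEL_SET = {
    "intercept": "",
    "day": "day",
    "obs_per": "obs_period_f",
    "obs_per + day": "obs_period_f + day",
    "veg.height": "veg_height",
    "veg.height + veg.cover": "veg_height + veg_cover_class",
    "veg.height + obs.per": "veg_height + obs_period_f",
    "crop + veg.height": "crop_type + veg_height",
    "crop + veg.height + veg.cover": "crop_type + veg_height + veg_cover_class",
}

ASSOCIATION_TERMS = {"earthworm": "earthworms", "waders": "waders",
                     "gulls": "other_gulls"}


def derive_presence(obs: pd.DataFrame) -> pd.DataFrame:
    """Add lbbg_present (count > 0), waders and other_gulls sums.

    Idempotent and row-conserving; obs_period is also exposed as a
    categorical ``obs_period_f`` (reference = first period).
    """
    out = obs.copy()
    out["lbbg_present"] = (out["lesser_black_backed_gull"] > 0).astype(int)
    out["waders"] = out[WADERS].sum(axis=1)
    out["other_gulls"] = out[OTHER_GULLS].sum(axis=1)
    periods = sorted(out["obs_period"].unique())
    out["obs_period_f"] = pd.Categorical(out["obs_period"].astype(str),
                                         categories=[str(p) for p in periods])
    return out


def _formula(fixed: str) -> str:
    rhs = fixed if fixed else "1"
    return f"lbbg_present ~ {rhs} + (1|transect_id/field_id)"


def fit_field_models(table: pd.DataFrame,
                     model_set: dict[str, str] | None = None,
                     best_for_association: str | None = None,
                     ) -> tuple[pd.DataFrame, dict[str, GlmmFit]]:
    """Fit and AICc-rank the presence model set (plus association models).

    When ``best_for_association`` names a model in the set, three further
    models are fitted adding earthworm, wader and other-gull counts to it.
    Returns the ranking table and the fits keyed by model name.
    """
    if model_set is None:
        model_set = dict(DEFAULT_MODEL_SET)
    if "lbbg_present" not in table.columns:
        table = derive_presence(table)
    fits: dict[str, GlmmFit] = {}
    for name, fixed in model_set.items():
        fits[name] = fit_glmm(table, _formula(fixed))
    if best_for_association is not None:
        base = model_set[best_for_association]
        for label, col in ASSOCIATION_TERMS.items():
            fixed = f"{base} + {col}" if base else col
            fits[f"{best_for_association} + {label}"] = fit_glmm(
                table, _formula(fixed))
    return rank_models(fits), fits
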