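"""Sensor-based ranking of enzyme variants and fluorescence-titer concordance.

Variants are ranked by mean fluorescence (ties broken lexicographically by
variant id). Concordance with directly measured titers uses the Spearman
rank correlation: the sensor transfer function is monotone but nonlinear, so
rank agreement — not linearity — is the claim a screen relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import VariantRecord
from .errors import EstimationError


@dataclass
class ScreenResult:
    table: pd.DataFrame  # ranked variants: variant_id, fluorescence, titer, cv, rank
    rank_correlation: float | None
    p_value: float | None
    dynamic_range: float | None  # max/min mean fluorescence; None if min <= 0
    top_variant: str


def _summarize(variants) -> pd.DataFrame:
    if isinstance(variants, pd.DataFrame):
        df = variants
        if "variant_id" not in df.columns or "fluorescence" not in df.columns:
            raise EstimationError("variant table needs variant_id and fluorescence columns")
        agg: dict[str, object] = {"fluorescence": ["mean", "std", "count"]}
        has_titer = "titer" in df.columns
        g = df.groupby("variant_id")
        out = pd.DataFrame(
            {
                "variant_id": list(g.groups),
                "fluorescence": g["fluorescence"].mean().to_numpy(),
                "n_replicates": g["fluorescence"].count().to_numpy(),
            }
        )
        sd = g["fluorescence"].std(ddof=1).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            out["cv"] = np.where(out["n_replicates"] >= 2, sd / out["fluorescence"], np.nan)
        out["titer"] = g["titer"].mean().to_numpy() if has_titer else np.nan
        return out
    records: Sequence[VariantRecord] = list(variants)
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "fluorescence": [r.fluorescence for r in records],
            "n_replicates": [r.n_replicates for r in records],
            "cv": [r.cv if r.cv is not None else np.nan for r in records],
            "titer": [r.titer if r.titer is not None else np.nan for r in records],
        }
    )


def rank_variants(variants) -> ScreenResult:
    """Rank variants by mean fluorescence and test fluorescence-titer
    concordance.

    ``variants`` is either a tidy replicate table (variant_id, fluorescence,
    optional titer) or a sequence of VariantRecord summaries.
    """
    df = _summarize(variants)
    if len(df) < 2:
        raise EstimationError("need at least 2 variants to rank")
    df = df.sort_values(
        ["fluorescence", "variant_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)

    rho = p = None
    if df["titer"].notna().all():
        rho_, p_ = stats.spearmanr(df["fluorescence"], df["titer"])
        rho, p = float(rho_), float(p_)

    fmin, fmax = float(df["fluorescence"].min()), float(df["fluorescence"].max())
    dyn = fmax / fmin if fmin > 0 else None
    return ScreenResult(
        table=df,
        rank_correlation=rho,
        p_value=p,
        dynamic_range=dyn,
        top_variant=str(df.loc[0, "variant_id"]),
    )
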