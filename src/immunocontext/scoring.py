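"""Ordinal density scoring, dichotomization and biomarker combinations.

Immune-cell infiltration per compartment is graded from the positive-cell
fraction (percent of all nucleated cells) on the conventional 0-3+ scale:

* 0 (absent): exactly 0%
* 1+ (mild): < 10%
* 2+ (moderate): 10-50% (left-closed: 10 maps to 2+)
* 3+ (marked): 50-100% (50 maps to 3+)

and dichotomized as high (2+, 3+) versus low (0, 1+).  Tumor-cell markers
use fixed or cohort-derived cut-offs: PD-L1/PD-L2 positive at >= 5% stained
tumor cells, beta-catenin overexpressed strictly above the cohort median of
membranous staining.  Pairs of dichotomies combine into three prognostic
groups running from immune-favorable (group 1) to immune-hostile (group 3).

Not-evaluable (NE) inputs are ``None``/NaN and propagate: any combination
or dichotomy with an NE input is NE (returned as ``None``/NaN).
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError

SCORE_MILD_PCT = 10.0
SCORE_MARKED_PCT = 50.0
PDL_CUTOFF_PCT = 5.0


def _is_na(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def score_density(positive_fraction_pct: float) -> int:
    """Ordinal 0-3+ score from a positive-cell fraction in percent."""
    f = float(positive_fraction_pct)
    if not 0.0 <= f <= 100.0:
        raise DataError(f"fraction {f} outside [0, 100]")
    if f == 0.0:
        return 0
    if f < SCORE_MILD_PCT:
        return 1
    if f < SCORE_MARKED_PCT:
        return 2
    return 3


def dichotomize_score(score: int) -> str:
    """High (2+, 3+) versus low (0, 1+)."""
    if score not in (0, 1, 2, 3):
        raise DataError(f"score must be 0-3, got {score}")
    return "high" if score >= 2 else "low"


def score_fractions(fractions_pct: Iterable[float]) -> np.ndarray:
    """Vectorized :func:`score_density`; NaN propagates as -1 -> NaN."""
    f = np.asarray(list(fractions_pct), dtype=float)
    ok = ~np.isnan(f)
    if np.any((f[ok] < 0) | (f[ok] > 100)):
        raise DataError("fractions outside [0, 100]")
    score = np.select(
        [f == 0, f < SCORE_MILD_PCT, f < SCORE_MARKED_PCT, f <= 100.0],
        [0, 1, 2, 3], default=np.nan).astype(float)
    score[~ok] = np.nan
    return score


def combine_cd8_cd163(cd8_dichot: str | None,
                      cd163_dichot: str | None) -> int | None:
    """Three-group CD8 x CD163 immunophenotype.

    Group 1: high CD8 / low CD163; group 2: both high or both low;
    group 3: low CD8 / high CD163.  NE input -> None.
    """
    if _is_na(cd8_dichot) or _is_na(cd163_dichot):
        return None
    pair = (cd8_dichot, cd163_dichot)
    mapping = {("high", "low"): 1, ("high", "high"): 2,
               ("low", "low"): 2, ("low", "high"): 3}
    if pair not in mapping:
        raise DataError(f"dichotomies must be 'high'/'low', got {pair}")
    return mapping[pair]


def combine_cd8_pdl1(pdl1_pct: float | None,
                     cd8_dichot: str | None,
                     cutoff_pct: float = PDL_CUTOFF_PCT) -> int | None:
    """Three-group PD-L1 x CD8 scheme.

    Group 1: PD-L1 >= cutoff and low CD8; group 2: both or neither;
    group 3: PD-L1 < cutoff and high CD8.
    """
    if _is_na(pdl1_pct) or _is_na(cd8_dichot):
        return None
    pos = float(pdl1_pct) >= cutoff_pct
    high = _check_dichot(cd8_dichot) == "high"
    if pos and not high:
        return 1
    if pos == high:
        return 2
    return 3


def combine_cd8_bcat(bcat_over: bool | None,
                     cd8_dichot: str | None) -> int | None:
    """Three-group beta-catenin x CD8 scheme.

    Group 1: beta-catenin overexpressed and low CD8; group 2: both or
    neither; group 3: not overexpressed and high CD8.
    """
    if _is_na(bcat_over) or _is_na(cd8_dichot):
        return None
    over = bool(bcat_over)
    high = _check_dichot(cd8_dichot) == "high"
    if over and not high:
        return 1
    if over == high:
        return 2
    return 3


def _check_dichot(value: str) -> str:
    if value not in ("high", "low"):
        raise DataError(f"dichotomy must be 'high'/'low', got {value!r}")
    return value


def dichotomize_tumor_markers(cohort: pd.DataFrame,
                              pdl_cutoff_pct: float = PDL_CUTOFF_PCT,
                              bcat_cutoff_pct: float | None = None
                              ) -> pd.DataFrame:
    """Add PD-L1/PD-L2/beta-catenin dichotomies to a percentage table.

    Expects (any subset of) columns ``pdl1_pct``, ``pdl2_pct`` and
    ``bcat_membranous_pct`` with NaN for not-evaluable patients.  PD-L1 and
    PD-L2 are positive at >= ``pdl_cutoff_pct``.  Beta-catenin is
    overexpressed strictly above the cut-off, which defaults to the cohort
    median of the evaluable membranous percentages; pass
    ``bcat_cutoff_pct`` to override with a fixed value.  NE propagates.
    """
    out = cohort.copy()
    for col, flag in (("pdl1_pct", "pdl1_pos"), ("pdl2_pct", "pdl2_pos")):
        if col in out.columns:
            pct = out[col].astype(float)
            if pct.notna().sum() == 0:
                raise DataError(f"{col}: no evaluable patients")
            _check_pct_range(pct, col)
            out[flag] = (pct >= pdl_cutoff_pct).where(pct.notna())
    if "bcat_membranous_pct" in out.columns:
        pct = out["bcat_membranous_pct"].astype(float)
        if pct.notna().sum() == 0:
            raise DataError("bcat_membranous_pct: no evaluable patients")
        _check_pct_range(pct, "bcat_membranous_pct")
        cutoff = (float(np.nanmedian(pct.to_numpy()))
                  if bcat_cutoff_pct is None else float(bcat_cutoff_pct))
        out["bcat_cutoff_pct"] = cutoff
        out["bcat_over"] = (pct > cutoff).where(pct.notna())
    return out


def _check_pct_range(pct: pd.Series, name: str) -> None:
    vals = pct.dropna()
    if len(vals) and ((vals < 0).any() or (vals > 100).any()):
        raise DataError(f"{name}: percentages outside [0, 100]")


def score_marker_table(assessments: pd.DataFrame,
                       fraction_col: str = "positive_fraction_pct"
                       ) -> pd.DataFrame:
    """Score a per-patient/marker/compartment fraction table.

    Adds ``score`` (0-3, NaN if NE) and ``dichot`` ('high'/'low'/NaN).
    """
    out = assessments.copy()
    scores = score_fractions(out[fraction_col].astype(float))
    out["score"] = scores
    out["dichot"] = pd.Series(
        np.where(np.isnan(scores), None,
                 np.where(scores >= 2, "high", "low")),
        index=out.index, dtype=object)
    return out
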