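"""Two-colour microarray m/a analysis, qPCR fold changes, and target integration.

Per spot, m = log2(test/reference) with the dye orientation resolved so that
positive m always means higher expression under the test condition, and
a = 0.5*log2(test*reference).  Arrays are normalized by subtracting a LOWESS
fit of m on a (per array), which removes intensity-dependent dye bias.  A
gene is called differentially expressed when at least ``min_sig`` of its
``n_expected`` replicate spots are individually significant at ``alpha`` and
its mean m clears the (inclusive) cut-off of +/-1.0, i.e. a two-fold change.
qPCR fold changes follow the crossing-point rule 2^-dCP with
dCP = mean(CP_test) - mean(CP_control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_SIG = 6
DEFAULT_N_EXPECTED = 8
DEFAULT_CUTOFF = 1.0
DEFAULT_LOWESS_FRAC = 0.4

SPOT_COLUMNS = ["gene_id", "array_id", "dye_orientation", "intensity_test", "intensity_ref"]
# dye_orientation: 'test=Cy5' or 'test=Cy3'; purely bookkeeping once intensities
# are stored condition-wise, but kept so raw channel tables can be ingested.


def compute_ma(intensity_test: float, intensity_ref: float) -> tuple[float, float]:
    """(m, a) for one spot; both intensities must be positive."""
    if intensity_test <= 0 or intensity_ref <= 0:
        raise ValueError("nonpositive spot intensity")
    m = float(np.log2(intensity_test / intensity_ref))
    a = float(0.5 * np.log2(intensity_test * intensity_ref))
    return m, a


def spots_to_ma(spots: pd.DataFrame) -> pd.DataFrame:
    """Add m and a columns; spots with nonpositive intensity are flagged and excluded.

    Input may store raw channel intensities (columns ``intensity_cy5``/
    ``intensity_cy3`` plus ``dye_orientation``) or condition-wise intensities
    (``intensity_test``/``intensity_ref``); orientation is resolved so m > 0
    means higher in the test condition either way.
    """
    df = spots.copy()
    if "intensity_test" not in df.columns:
        is_cy5 = df["dye_orientation"].eq("test=Cy5")
        df["intensity_test"] = np.where(is_cy5, df["intensity_cy5"], df["intensity_cy3"])
        df["intensity_ref"] = np.where(is_cy5, df["intensity_cy3"], df["intensity_cy5"])
    ok = (df["intensity_test"] > 0) & (df["intensity_ref"] > 0)
    if not ok.all():
        df = df[ok].copy()
    df["m"] = np.log2(df["intensity_test"] / df["intensity_ref"])
    df["a"] = 0.5 * np.log2(df["intensity_test"] * df["intensity_ref"])
    return df


def lowess_normalize(
    spots: pd.DataFrame,
    frac: float = DEFAULT_LOWESS_FRAC,
    min_spots: int = 20,
) -> pd.DataFrame:
    """Subtract a per-array LOWESS fit of m on a from each spot's m.

    Arrays with fewer than ``min_spots`` spots are passed through unchanged.
    """
    df = spots.copy()
    out = []
    for _, sub in df.groupby("array_id", sort=False):
        sub = sub.copy()
        if len(sub) < min_spots:
            logging.getLogger("regulonkit").warning(
                "array with %d spots: too few for normalization, skipped", len(sub)
            )
        else:
            fitted = lowess(
                sub["m"].to_numpy(), sub["a"].to_numpy(),
                frac=frac, return_sorted=False,
            )
            sub["m"] = sub["m"].to_numpy() - fitted
        out.append(sub)
    return pd.concat(out, ignore_index=True)


@dataclass
class GeneExpressionCall:
    gene_id: str
    m_mean: float
    a_mean: float
    n_spots: int
    n_significant: int
    call: str  # up / down / unchanged / filtered


def _spot_significance(m: np.ndarray, alpha: float) -> int:
    """Count spots individually significant against m=0.

    Each spot's m is referred to the replicate scatter: t_i = m_i / s with
    s the sample standard deviation of the gene's replicate m values,
    two-sided p from Student's t with n-1 degrees of freedom.
    """
    n = m.size
    if n < 2:
        return 0
    s = m.std(ddof=1)
    if s == 0:
        return n if abs(m[0]) > 0 else 0
    t = m / s
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    return int((p < alpha).sum())


def call_differential(
    spots: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_sig: int = DEFAULT_MIN_SIG,
    n_expected: int = DEFAULT_N_EXPECTED,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Per-gene differential-expression calls from normalized spot m values.

    A gene passes the replicate filter when >= ``min_sig`` of its spots are
    individually significant at ``alpha`` (genes with fewer than ``min_sig``
    spots are 'filtered'); passing genes are called by mean m against the
    inclusive cut-offs (m >= cutoff: up; m <= -cutoff: down).
    """
    calls = []
    for gene_id, sub in spots.groupby("gene_id", sort=True):
        m = sub["m"].to_numpy(dtype=float)
        a_mean = float(sub["a"].mean()) if "a" in sub.columns else float("nan")
        n_sig = _spot_significance(m, alpha)
        m_mean = float(m.mean())
        if len(m) < min_sig or n_sig < min_sig:
            call = "filtered"
        elif m_mean >= cutoff:
            call = "up"
        elif m_mean <= -cutoff:
            call = "down"
        else:
            call = "unchanged"
        calls.append(GeneExpressionCall(gene_id, m_mean, a_mean, len(m), n_sig, call))
    return pd.DataFrame([vars(c) for c in calls])


def call_from_summary(table: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Calls from per-gene mean m values with the replicate filter taken as passed.

    Used when only summary m values (not spot-level replicates) are available,
    e.g. published expression tables.  Expects columns gene_id / m_mean.
    """
    df = table.copy()
    df["call"] = np.select(
        [df["m_mean"] >= cutoff, df["m_mean"] <= -cutoff],
        ["up", "down"],
        default="unchanged",
    )
    return df


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def rtpcr_fold_change(cp_test, cp_control) -> float:
    """Relative expression change 2^-dCP from replicate crossing points."""
    dcp = float(np.mean(cp_test)) - float(np.mean(cp_control))
    return float(2.0 ** (-dcp))


def rtpcr_table(cp: pd.DataFrame) -> pd.DataFrame:
    """Per-gene fold changes from a long CP table (gene_id, condition, cp).

    ``condition`` is 'test' or 'control'.
    """
    rows = []
    for gene_id, sub in cp.groupby("gene_id", sort=True):
        test = sub.loc[sub["condition"] == "test", "cp"]
        control = sub.loc[sub["condition"] == "control", "cp"]
        if test.empty or control.empty:
            raise ValueError(f"gene {gene_id}: need CPs for both conditions")
        dcp = float(test.mean() - control.mean())
        rows.append({
            "gene_id": gene_id,
            "delta_cp": dcp,
            "fold_change": 2.0 ** (-dcp),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def integrate_targets(
    calls: pd.DataFrame,
    regulon_members: pd.DataFrame | None = None,
    rtpcr: pd.DataFrame | None = None,
    rtpcr_min_fold: float = 2.0,
) -> pd.DataFrame:
    """Join expression calls with predicted regulon membership.

    Labels: 'direct' (up-regulated and in a site-bearing TU), 'indirect'
    (up-regulated, no site), 'down', 'unchanged', and
    'site_without_expression_support' for site-bearing genes that are not
    up-regulated (the pattern the adhA locus shows).  When an rtpcr table is
    given, an ``rtpcr_confirmed`` column marks genes whose qPCR fold change
    reaches ``rtpcr_min_fold``.
    """
    df = calls.copy()
    site_genes = (
        set(regulon_members["gene_id"]) if regulon_members is not None else set()
    )
    labels = []
    for row in df.itertuples(index=False):
        has_site = row.gene_id in site_genes
        if row.call == "up":
            labels.append("direct" if has_site else "indirect")
        elif has_site:
            labels.append("site_without_expression_support")
        elif row.call == "down":
            labels.append("down")
        else:
            labels.append("unchanged")
    df["target_label"] = labels
    if rtpcr is not None:
        folds = rtpcr.set_index("gene_id")["fold_change"]
        df["rtpcr_fold"] = df["gene_id"].map(folds)
        df["rtpcr_confirmed"] = df["rtpcr_fold"] >= rtpcr_min_fold
    return df
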