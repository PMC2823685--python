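"""Bundled published expression/motif tables for the *C. glutamicum* Zur regulon.

Two small TSVs ship with the package: the nine direct Zur target genes
(five 21-bp operator sites, array m-values and qPCR fold changes) and the
seventeen additional differentially expressed genes without operator sites
(array m-values; qPCR fold change or 'n.s.' where the signal was not
significant).  They serve as fixed inputs for the differential-expression
filters and as the motif training set.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("regulonkit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_direct_targets() -> pd.DataFrame:
    """Nine direct Zur target genes: cds, gene, product, motif, m_array, rtpcr_fold.

    ``motif`` is '-' for genes inside operons without their own site; m and
    fold columns are numeric.
    """
    df = _load("zur_direct_targets.tsv")
    df["m_array"] = df["m_array"].astype(float)
    df["rtpcr_fold"] = df["rtpcr_fold"].astype(float)
    return df


def load_secondary_targets() -> pd.DataFrame:
    """Seventeen differentially expressed genes lacking operator sites.

    ``rtpcr_fold`` is NaN where the qPCR signal was not significant ('n.s.').
    """
    df = _load("zur_secondary_targets.tsv")
    df["m_array"] = df["m_array"].astype(float)
    df["rtpcr_fold"] = pd.to_numeric(df["rtpcr_fold"], errors="coerce")
    return df


def training_motifs() -> list[str]:
    """The five published 21-bp operator sites, in table order."""
    df = load_direct_targets()
    return [m for m in df["motif"] if m != "-"]
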