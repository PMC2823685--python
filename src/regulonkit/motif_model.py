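"""Positional-weight-matrix model of a transcription-factor binding motif.

Counts N(b,k) are accumulated per column from a training set of aligned
W-mers; for palindromic motifs each site also contributes its reverse
complement, which makes forward and reverse scan scores identical by
construction.  Weights are centred log counts,

    w(b,k) = ln(N(b,k) + c) - (1/4) * sum_b' ln(N(b',k) + c),

with pseudocount c (default 0.5), so every column's weights sum to zero.
A candidate site's Z-score is the plain sum of positional weights, and the
scan threshold is the minimum score over the training sites.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .genome_io import revcomp

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes; any ambiguity code becomes 4."""
    return np.array([BASE_INDEX.get(ch, 4) for ch in seq.upper()], dtype=np.int64)


@dataclass(frozen=True)
class SiteScore:
    """A scored W-mer; ``z`` is -inf iff the sequence contains ambiguity codes."""

    sequence: str
    z: float


@dataclass
class MotifModel:
    """Width-W count matrix with derived positional weights and scan threshold.

    ``counts`` and ``weights`` are (W, 4) arrays over columns x bases (A,C,G,T).
    ``threshold`` is unset (None) until :func:`set_threshold_from_training`.
    """

    width: int
    counts: np.ndarray
    weights: np.ndarray
    palindromic: bool
    pseudocount: float
    threshold: float | None = None
    training_sites: list[str] = field(default_factory=list)

    # -- scoring -----------------------------------------------------------

    def score(self, seq: str) -> SiteScore:
        """Z-score of one W-mer: the sum of positional nucleotide weights."""
        if len(seq) != self.width:
            raise ValueError(f"expected a {self.width}-mer, got length {len(seq)}")
        codes = encode(seq)
        if (codes > 3).any():
            return SiteScore(seq, float("-inf"))
        return SiteScore(seq, float(self.weights[np.arange(self.width), codes].sum()))

    def score_value(self, seq: str) -> float:
        return self.score(seq).z

    # -- summaries ---------------------------------------------------------

    def frequencies(self) -> np.ndarray:
        """Pseudocounted per-column base frequencies (rows sum to 1)."""
        padded = self.counts + self.pseudocount
        return padded / padded.sum(axis=1, keepdims=True)

    def consensus(self) -> tuple[str, list[int]]:
        """Argmax base per column; returns (consensus, list of tied columns)."""
        letters = []
        ties = []
        for k in range(self.width):
            col = self.counts[k]
            best = col.max()
            winners = [i for i in range(4) if col[i] == best]
            if len(winners) > 1:
                ties.append(k)
            letters.append(BASES[winners[0]])  # alphabetical tie-break
        return "".join(letters), ties

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits: 2 + sum_b f log2 f."""
        f = self.frequencies()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + terms.sum(axis=1)

    def logo_table(self) -> pd.DataFrame:
        """Per-column base frequencies as a DataFrame (columns A,C,G,T)."""
        return pd.DataFrame(self.frequencies(), columns=list(BASES))

    # -- serialization -----------------------------------------------------

    def to_files(self, tsv_path: str | os.PathLike, json_path: str | os.PathLike) -> None:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.index.name = "position"
        df.to_csv(tsv_path, sep="\t")
        meta = {
            "width": self.width,
            "palindromic": self.palindromic,
            "pseudocount": self.pseudocount,
            "threshold": self.threshold,
            "training_sites": self.training_sites,
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def from_files(cls, tsv_path: str | os.PathLike, json_path: str | os.PathLike) -> "MotifModel":
        df = pd.read_csv(tsv_path, sep="\t", index_col=0)
        counts = df[list(BASES)].to_numpy(dtype=float)
        with open(json_path) as fh:
            meta = json.load(fh)
        model = cls(
            width=meta["width"],
            counts=counts,
            weights=weights_from_counts(counts, meta["pseudocount"]),
            palindromic=meta["palindromic"],
            pseudocount=meta["pseudocount"],
            threshold=meta["threshold"],
            training_sites=list(meta.get("training_sites", [])),
        )
        return model


def weights_from_counts(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """Centred log-count weights; each column (second axis) sums to zero.

    With ``pseudocount=0`` an unobserved base gets weight -inf (its windows
    can never match), which is intended.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(counts + pseudocount)
        return logs - logs.mean(axis=1, keepdims=True)


def symmetrized_counts(counts: np.ndarray) -> np.ndarray:
    """counts + its reverse complement (flip columns, swap complementary bases)."""
    return counts + counts[::-1, :][:, COMPLEMENT_INDEX]


def counts_from_sites(sites: list[str], width: int) -> np.ndarray:
    counts = np.zeros((width, 4), dtype=float)
    for site in sites:
        codes = encode(site)
        if (codes > 3).any():
            raise ValueError(f"training site contains non-ACGT character: {site}")
        counts[np.arange(width), codes] += 1.0
    return counts


def build_motif(
    sites: list[str],
    palindromic: bool = True,
    pseudocount: float = 0.5,
) -> MotifModel:
    """Build a PWM from aligned training sites.

    For ``palindromic=True`` the counts are symmetrized by also tallying each
    site's reverse complement, which enforces w(b,k) = w(comp(b), W-1-k) and
    hence strand-symmetric scores.  The threshold is left unset.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 training sites")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("training sites have inconsistent lengths")
    counts = counts_from_sites(list(sites), width)
    if palindromic:
        counts = symmetrized_counts(counts)
    return MotifModel(
        width=width,
        counts=counts,
        weights=weights_from_counts(counts, pseudocount),
        palindromic=palindromic,
        pseudocount=pseudocount,
        training_sites=list(sites),
    )


def model_from_counts(
    counts: np.ndarray,
    palindromic: bool,
    pseudocount: float = 0.5,
    training_sites: list[str] | None = None,
) -> MotifModel:
    """Assemble a model directly from a (W, 4) count matrix."""
    counts = np.asarray(counts, dtype=float)
    return MotifModel(
        width=counts.shape[0],
        counts=counts,
        weights=weights_from_counts(counts, pseudocount),
        palindromic=palindromic,
        pseudocount=pseudocount,
        training_sites=list(training_sites or []),
    )


def set_threshold_from_training(model: MotifModel) -> MotifModel:
    """Set the scan threshold to the minimum training-site score (in place).

    Every training site scores at or above the threshold by construction.
    """
    if not model.training_sites:
        raise ValueError("model has no training sites")
    model.threshold = min(model.score_value(s) for s in model.training_sites)
    return model


def read_meme_minimal(path: str | os.PathLike, effective_n: float = 20.0) -> list[MotifModel]:
    """Import MEME minimal-format motifs, converting frequencies to counts
    at a stated effective number of sites."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    models = []
    for m in parsed:
        freqs = np.array([[m.pwm[b][k] for b in BASES] for k in range(m.length)])
        models.append(model_from_counts(freqs * effective_n, palindromic=False))
    return models
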