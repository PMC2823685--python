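"""Genome scanning and cross-genome regulon assembly.

The scan scores every width-W window on both strands of each genome with the
PWM and keeps windows at or above the threshold.  Candidate sites are
assigned to every gene whose upstream window covers the site's centre (a
single site in a short intergenic gap can therefore serve two divergently
transcribed genes).  Genes are chained into transcription units (TUs) by the
usual co-directional intergenic-gap rule, candidates are filtered by the
cross-genome consistency check (a TU survives only if orthologues of its
genes carry candidate sites in at least K OTHER genomes), and finally every
gene of a surviving site-bearing TU becomes a regulon member, the non-lead
genes by operon inheritance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import DEFAULT_WINDOW, Gene, Genome, OrthologyMap, upstream_interval
from .motif_model import COMPLEMENT_INDEX, MotifModel, encode

logger = logging.getLogger("regulonkit")

DEFAULT_OPERON_GAP = 100
DEFAULT_MIN_SUPPORT = 2


@dataclass
class SiteInstance:
    """A candidate binding site placed on a genome's forward strand."""

    genome_id: str
    position: int  # 0-based leftmost coordinate of the W-mer
    strand: str
    sequence: str  # forward-strand slice
    z: float
    assigned_genes: dict[str, int] = field(default_factory=dict)  # gene_id -> offset of site centre to translation start

    def center(self, width: int | None = None) -> int:
        width = width if width is not None else len(self.sequence)
        return self.position + width // 2


@dataclass
class TranscriptionUnit:
    """Maximal run of co-directional genes with small intergenic gaps."""

    tu_id: str
    gene_ids: list[str]  # 5'->3' in transcription order
    strand: str
    sites: list[SiteInstance] = field(default_factory=list)

    @property
    def lead_gene(self) -> str:
        return self.gene_ids[0]


@dataclass
class RegulonMember:
    genome_id: str
    tu_id: str
    gene_id: str
    evidence: str  # 'direct_site' or 'operon_inherited'
    consistency_support: int
    best_z: float


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _window_scores(weights: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scores of all forward windows; windows touching an ambiguity code -> -inf."""
    W = weights.shape[0]
    n = codes.size
    if n < W:
        return np.empty(0)
    # 5th row handles ambiguity codes: any N in the window forces -inf
    lut = np.vstack([weights.T, np.full((1, W), -np.inf)])  # (5, W)
    scores = np.zeros(n - W + 1)
    for k in range(W):
        scores += lut[codes[k : n - W + 1 + k], k]
    return scores


def scan_sequence(
    model: MotifModel,
    genome: Genome,
    threshold: float | None = None,
) -> list[SiteInstance]:
    """Score every window of width W on both strands; keep z >= threshold.

    For palindromic models the forward and reverse scores at one locus are
    identical, and the locus is reported once with strand '+'.  Results are
    sorted by position.
    """
    if threshold is None:
        threshold = model.threshold
    if threshold is None:
        raise ValueError("model threshold unset and no explicit threshold given")
    W = model.width
    codes = encode(genome.sequence)
    fwd = _window_scores(model.weights, codes)
    # reverse-strand score at leftmost position i equals the forward score of
    # the complement-reversed weight matrix
    rc_weights = model.weights[::-1, :][:, COMPLEMENT_INDEX]
    rev = _window_scores(rc_weights, codes)

    # summation-order rounding must not reject a window at the exact threshold
    # (the training-minimum site scores exactly Z_min by construction)
    eps = 1e-9 * max(1.0, abs(threshold))
    sites: list[SiteInstance] = []
    for i in range(fwd.size):
        hit_f = fwd[i] >= threshold - eps
        hit_r = rev[i] >= threshold - eps
        if not (hit_f or hit_r):
            continue
        seq = genome.sequence[i : i + W]
        if model.palindromic:
            sites.append(SiteInstance(genome.genome_id, i, "+", seq, float(fwd[i])))
        else:
            if hit_f:
                sites.append(SiteInstance(genome.genome_id, i, "+", seq, float(fwd[i])))
            if hit_r:
                sites.append(SiteInstance(genome.genome_id, i, "-", seq, float(rev[i])))
    return sites


# ---------------------------------------------------------------------------
# Assignment and transcription units
# ---------------------------------------------------------------------------

def assign_sites_to_genes(
    sites: list[SiteInstance],
    genome: Genome,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> list[SiteInstance]:
    """Assign each site to every gene whose upstream window covers its centre.

    Returns only the sites that hit at least one window; a divergent gene
    pair with a site centred in the shared intergenic gap receives the same
    site on both genes.  The recorded per-gene offset is the signed distance
    from the site centre to the translation start in gene orientation
    (negative = upstream).
    """
    kept: list[SiteInstance] = []
    for site in sites:
        center = site.center()
        for gene in genome.genes:
            lo, hi = upstream_interval(genome, gene, window)
            if lo <= center < hi:
                if gene.strand == "+":
                    offset = center - gene.translation_start
                else:
                    offset = gene.translation_start - center
                site.assigned_genes[gene.gene_id] = offset
        if site.assigned_genes:
            kept.append(site)
        else:
            logger.info(
                "site at %s:%d (z=%.2f) covers no upstream window; dropped",
                site.genome_id, site.position, site.z,
            )
    return kept


def build_transcription_units(
    genome: Genome,
    operon_gap: int = DEFAULT_OPERON_GAP,
) -> list[TranscriptionUnit]:
    """Greedy chaining of co-directional genes with intergenic gap <= operon_gap.

    Every gene lands in exactly one TU; gene order inside a TU follows the
    direction of transcription.
    """
    units: list[TranscriptionUnit] = []
    chain: list[Gene] = []

    def flush() -> None:
        if not chain:
            return
        strand = chain[0].strand
        ordered = chain if strand == "+" else chain[::-1]
        tu_id = f"{genome.genome_id}:TU{len(units):03d}"
        units.append(TranscriptionUnit(tu_id, [g.gene_id for g in ordered], strand))

    for gene in genome.genes:  # sorted by start
        if chain and gene.strand == chain[-1].strand and gene.start - chain[-1].end <= operon_gap:
            chain.append(gene)
        else:
            flush()
            chain = [gene]
    flush()
    return units


def _attach_sites_to_tus(
    units: list[TranscriptionUnit],
    sites: list[SiteInstance],
) -> None:
    by_gene: dict[str, TranscriptionUnit] = {
        g: tu for tu in units for g in tu.gene_ids
    }
    for tu in units:
        tu.sites = []
    for site in sites:
        seen: set[str] = set()
        for gene_id in site.assigned_genes:
            tu = by_gene.get(gene_id)
            if tu is not None and tu.tu_id not in seen:
                tu.sites.append(site)
                seen.add(tu.tu_id)


# ---------------------------------------------------------------------------
# Consistency check
# ---------------------------------------------------------------------------

def consistency_filter(
    candidates_by_genome: dict[str, list[TranscriptionUnit]],
    orthology: OrthologyMap,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> dict[str, list[TranscriptionUnit]]:
    """Retain a candidate TU iff orthologues of >=1 of its genes carry
    candidate sites in >= min_support OTHER genomes.

    Support counts genomes other than the candidate's own; K=0 is the
    identity.  Returns {genome_id: [TU, ...]} with consistency support
    stored on each TU as attribute ``support``.
    """
    # genomes in which each family has >=1 site-bearing candidate gene
    family_hits: dict[str, set[str]] = {}
    for genome_id, units in candidates_by_genome.items():
        for tu in units:
            if not tu.sites:
                continue
            for gene_id in tu.gene_ids:
                fam = orthology.family_of(genome_id, gene_id)
                if fam is None:
                    logger.warning(
                        "gene %s (%s) absent from orthology; support 0",
                        gene_id, genome_id,
                    )
                    continue
                family_hits.setdefault(fam, set()).add(genome_id)

    filtered: dict[str, list[TranscriptionUnit]] = {}
    for genome_id, units in candidates_by_genome.items():
        kept = []
        for tu in units:
            if not tu.sites:
                continue
            support = 0
            supporting: set[str] = set()
            for gene_id in tu.gene_ids:
                fam = orthology.family_of(genome_id, gene_id)
                if fam is not None:
                    supporting |= family_hits.get(fam, set()) - {genome_id}
            support = len(supporting)
            tu.support = support  # type: ignore[attr-defined]
            if support >= min_support:
                kept.append(tu)
        filtered[genome_id] = kept
    return filtered


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class ScanConfig:
    threshold: float | None = None  # None -> model's training-minimum
    window: tuple[int, int] = DEFAULT_WINDOW
    operon_gap: int = DEFAULT_OPERON_GAP
    min_support: int = DEFAULT_MIN_SUPPORT


def assemble_regulon(
    model: MotifModel,
    panel: dict[str, Genome],
    orthology: OrthologyMap | None,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Full pipeline: scan -> assign -> TUs -> consistency -> operon inheritance.

    Returns a tidy table of regulon members (one row per genome/TU/gene) with
    evidence flags and cross-genome support.  Passing ``orthology=None`` (or
    ``min_support=0``) skips the consistency check, which a single-genome run
    requires.
    """
    config = config or ScanConfig()
    if orthology is not None:
        orthology.validate(panel)

    candidates: dict[str, list[TranscriptionUnit]] = {}
    for genome_id, genome in panel.items():
        sites = scan_sequence(model, genome, threshold=config.threshold)
        sites = assign_sites_to_genes(sites, genome, window=config.window)
        units = build_transcription_units(genome, operon_gap=config.operon_gap)
        _attach_sites_to_tus(units, sites)
        candidates[genome_id] = units

    if orthology is not None and config.min_support > 0:
        filtered = consistency_filter(candidates, orthology, config.min_support)
    else:
        filtered = {
            gid: [tu for tu in units if tu.sites]
            for gid, units in candidates.items()
        }
        for units in filtered.values():
            for tu in units:
                tu.support = 0  # type: ignore[attr-defined]

    rows = []
    for genome_id, units in filtered.items():
        genome = panel[genome_id]
        for tu in units:
            best_z = max(s.z for s in tu.sites)
            direct = {g for s in tu.sites for g in s.assigned_genes if g in tu.gene_ids}
            for gene_id in tu.gene_ids:
                rows.append(
                    RegulonMember(
                        genome_id=genome_id,
                        tu_id=tu.tu_id,
                        gene_id=gene_id,
                        evidence="direct_site" if gene_id in direct else "operon_inherited",
                        consistency_support=getattr(tu, "support", 0),
                        best_z=best_z,
                    )
                )
    df = pd.DataFrame(
        [vars(m) for m in rows],
        columns=["genome_id", "tu_id", "gene_id", "evidence",
                 "consistency_support", "best_z"],
    )
    return df.sort_values(["genome_id", "tu_id", "gene_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def sites_to_bed(sites: list[SiteInstance], width: int) -> pd.DataFrame:
    """BED6 rows; score = 100*z clamped to [0, 1000]."""
    rows = []
    for s in sites:
        rows.append({
            "chrom": s.genome_id,
            "start": s.position,
            "end": s.position + width,
            "name": ";".join(sorted(s.assigned_genes)) or "unassigned",
            "score": int(np.clip(100 * s.z, 0, 1000)),
            "strand": s.strand,
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def sites_to_table(sites: list[SiteInstance]) -> pd.DataFrame:
    """Per assigned gene: motif sequence, Z-score, and offset to translation start."""
    rows = []
    for s in sites:
        for gene_id, offset in sorted(s.assigned_genes.items()):
            rows.append({
                "genome_id": s.genome_id,
                "gene_id": gene_id,
                "motif": s.sequence,
                "z": s.z,
                "offset_to_start": offset,
                "position": s.position,
                "strand": s.strand,
            })
    return pd.DataFrame(
        rows,
        columns=["genome_id", "gene_id", "motif", "z", "offset_to_start", "position", "strand"],
    )
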