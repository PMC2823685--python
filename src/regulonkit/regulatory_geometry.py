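"""Site-vs-promoter geometry, leaderless transcripts, and band-shift probes.

A repressor-compatible operator overlaps the core promoter (-35 alone or the
whole -10/-35 region), where bound protein occludes RNA polymerase; a site
that overlaps neither element is classified distal with its strand-aware
distance to the transcription start, negative when the site lies downstream
of it.  Probes for band-shift assays are 40-mers carrying the 21-bp site in
the centre of native genomic flanks; mutant probes carry transitions
(A<->G, C<->T), which are involutions, in either the motif or the flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import Gene, Genome
from .regulon_scan import SiteInstance

TRANSITION = str.maketrans("ACGT", "GTAC")  # A<->G, C<->T


@dataclass
class PromoterAnnotation:
    """User-supplied promoter map: TSS plus optional -10/-35 intervals.

    All coordinates 0-based on the forward strand; ``tss`` is the base of +1.
    Intervals are half-open.
    """

    gene_id: str
    tss: int
    strand: str
    minus10: tuple[int, int] | None = None
    minus35: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"promoter {self.gene_id}: bad strand {self.strand!r}")
        if self.minus10 and self.minus35:
            if self.strand == "+":
                ok = self.minus35[1] <= self.minus10[0] and self.minus10[1] <= self.tss + 1
            else:
                ok = self.minus10[0] >= self.tss and self.minus35[0] >= self.minus10[1]
            if not ok:
                raise ValueError(
                    f"promoter {self.gene_id}: -35/-10/TSS order violated"
                )


@dataclass
class SitePlacement:
    """Classification of one site against one promoter."""

    kind: str  # 'overlaps_core' | 'overlaps_minus35' | 'distal'
    distance: int | None = None  # set for distal: nt from site's downstream edge to TSS
    downstream_of_tss: bool = False


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_site_vs_promoter(
    site: SiteInstance,
    promoter: PromoterAnnotation,
    width: int = 21,
) -> SitePlacement:
    """Place a site against a mapped promoter.

    'overlaps_core' when the site touches both the -10 and -35 elements,
    'overlaps_minus35' when it touches -35 only; otherwise 'distal' with the
    strand-aware distance from the site's downstream edge (the edge nearest
    the gene) to the TSS.  Distal placements are repression-incompatible;
    a negative distance means the site lies downstream of the TSS and is
    flagged.  Both overlap classes require the promoter elements.
    """
    interval = (site.position, site.position + width)
    hits10 = promoter.minus10 is not None and _overlap(interval, promoter.minus10)
    hits35 = promoter.minus35 is not None and _overlap(interval, promoter.minus35)
    if hits35 and hits10:
        return SitePlacement("overlaps_core")
    if hits35:
        return SitePlacement("overlaps_minus35")
    if hits10:
        # -10 alone still occludes the core promoter
        return SitePlacement("overlaps_core")
    if promoter.strand == "+":
        d = promoter.tss - interval[1] + 1  # downstream edge = last base of site
    else:
        d = interval[0] - promoter.tss
    return SitePlacement("distal", distance=d, downstream_of_tss=d < 0)


def detect_leaderless(promoter: PromoterAnnotation, gene: Gene) -> bool:
    """True iff transcription starts on the first base of the start codon."""
    if promoter.strand != gene.strand:
        raise ValueError(
            f"promoter/gene strand mismatch for {gene.gene_id}"
        )
    return promoter.tss == gene.translation_start


@dataclass
class Probe:
    """A band-shift oligo: the site embedded centrally in native flanks."""

    sequence: str
    motif_offset: int
    mutated_positions: frozenset[int] = field(default_factory=frozenset)

    def motif(self, width: int = 21) -> str:
        return self.sequence[self.motif_offset : self.motif_offset + width]


def design_probe(genome: Genome, site: SiteInstance, probe_len: int = 40) -> Probe:
    """Cut a ``probe_len``-mer with the site's 21-mer centred in native sequence.

    The left flank takes the extra base when the split is uneven (10/9 for a
    40-mer around a 21-bp site).
    """
    width = len(site.sequence)
    left = -(-(probe_len - width) // 2)  # ceil
    right = probe_len - width - left
    start = site.position - left
    end = site.position + width + right
    if start < 0 or end > len(genome):
        deficit = max(0 - start, end - len(genome))
        raise ValueError(
            f"site at {site.position} lacks {deficit} nt of native flank "
            f"for a {probe_len}-mer probe"
        )
    return Probe(sequence=genome.sequence[start:end], motif_offset=left)


def mutate_probe(
    probe: Probe,
    region: str = "motif",
    positions: set[int] | None = None,
    width: int = 21,
) -> Probe:
    """Apply transition mutations within the motif or the flanks.

    ``positions`` are probe coordinates; by default every position of the
    chosen region is mutated.  Transitions are involutions, so applying the
    same mutation twice restores the original probe.
    """
    motif_range = range(probe.motif_offset, probe.motif_offset + width)
    if positions is None:
        if region == "motif":
            positions = set(motif_range)
        elif region == "flanks":
            positions = set(range(len(probe.sequence))) - set(motif_range)
        else:
            raise ValueError(f"unknown region {region!r}")
    bad = [p for p in positions if not 0 <= p < len(probe.sequence)]
    if bad:
        raise ValueError(f"positions outside probe: {sorted(bad)}")
    seq = list(probe.sequence)
    for p in positions:
        seq[p] = seq[p].translate(TRANSITION)
    return Probe(
        sequence="".join(seq),
        motif_offset=probe.motif_offset,
        mutated_positions=frozenset(probe.mutated_positions ^ set(positions)),
    )
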