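"""Genome panels, annotations, orthology tables and upstream-region extraction.

Coordinates are 0-based half-open on the forward strand everywhere inside the
package.  GFF3 (1-based inclusive) and the optional 1-based TSV annotation
dialect are converted at the I/O boundary.  Upstream windows are expressed
relative to the translation start: position 0 is the first base of the start
codon, negative offsets extend upstream in gene orientation.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("regulonkit")

VALID_BASES = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving N."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene on the forward-strand coordinate system.

    ``start``/``end`` form a 0-based half-open interval; ``strand`` is '+'
    or '-'.  For a '-' gene the translation start is the base at ``end - 1``.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: malformed strand {self.strand!r}")

    @property
    def translation_start(self) -> int:
        """Forward-strand coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Genome:
    """One annotated replicon: sequence plus genes sorted by start."""

    genome_id: str
    sequence: str
    genes: list[Gene] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - VALID_BASES
        if bad:
            raise ValueError(f"genome {self.genome_id}: invalid characters {bad}")
        self.sequence = self.sequence.upper()
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.gene_id))
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"genome {self.genome_id}: duplicate gene ids")
        if not self.circular:
            for g in self.genes:
                if g.end > len(self.sequence):
                    raise ValueError(
                        f"gene {g.gene_id} extends past end of linear genome "
                        f"{self.genome_id} ({g.end} > {len(self.sequence)})"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class UpstreamRegion:
    """Oriented upstream window of one gene.

    ``interval`` is on the forward strand (0-based half-open);
    ``oriented_sequence`` reads 5'->3' in the gene's own sense (reverse
    complemented for '-' genes).  ``truncated`` marks clipping at the edge
    of a linear contig; an entirely off-contig window yields an empty
    region with ``empty=True``.
    """

    gene_id: str
    genome_id: str
    interval: tuple[int, int]
    oriented_sequence: str
    truncated: bool = False
    empty: bool = False

    def __len__(self) -> int:
        return len(self.oriented_sequence)


class OrthologyMap:
    """family_id -> genome_id -> set of gene_id; each gene in at most one family."""

    def __init__(self, families: dict[str, dict[str, set[str]]]):
        self.families = families
        seen: dict[tuple[str, str], str] = {}
        for fam, by_genome in families.items():
            for genome_id, genes in by_genome.items():
                for gene_id in genes:
                    key = (genome_id, gene_id)
                    if key in seen and seen[key] != fam:
                        raise ValueError(
                            f"gene {gene_id} in genome {genome_id} assigned to two "
                            f"families: {seen[key]} and {fam}"
                        )
                    seen[key] = fam
        self._family_of = seen

    def family_of(self, genome_id: str, gene_id: str) -> str | None:
        return self._family_of.get((genome_id, gene_id))

    def members(self, family_id: str) -> dict[str, set[str]]:
        return self.families[family_id]

    def __len__(self) -> int:
        return len(self.families)

    def validate(self, panel: dict[str, Genome]) -> None:
        """Every referenced genome and gene must exist in the panel."""
        for fam, by_genome in self.families.items():
            for genome_id, genes in by_genome.items():
                if genome_id not in panel:
                    raise ValueError(f"family {fam}: unknown genome {genome_id}")
                known = {g.gene_id for g in panel[genome_id].genes}
                missing = genes - known
                if missing:
                    raise ValueError(
                        f"family {fam}: genes {sorted(missing)} absent from "
                        f"genome {genome_id}"
                    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _genes_from_gff3(path: str | os.PathLike, record_ids: set[str]) -> dict[str, list[Gene]]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out: dict[str, list[Gene]] = {rid: [] for rid in record_ids}
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        if feat.seqid not in record_ids:
            raise ValueError(f"annotation references unknown record {feat.seqid!r}")
        if feat.strand not in ("+", "-"):
            raise ValueError(f"feature {feat.id}: malformed strand {feat.strand!r}")
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        product = feat.attributes.get("product", [""])[0]
        # GFF3 is 1-based inclusive
        out[feat.seqid].append(
            Gene(gene_id, feat.start - 1, feat.end, feat.strand, product)
        )
    return out


def _genes_from_tsv(path: str | os.PathLike, record_ids: set[str]) -> dict[str, list[Gene]]:
    """4/5-column TSV: gene_id, start, end, strand[, genome_id]; 1-based inclusive
    when the header contains 'one_based', else 0-based half-open."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    one_based = any("one_based" in c for c in df.columns)
    only = next(iter(record_ids)) if len(record_ids) == 1 else None
    out: dict[str, list[Gene]] = {rid: [] for rid in record_ids}
    for row in df.itertuples(index=False):
        rid = getattr(row, "genome_id", only)
        if rid not in record_ids:
            raise ValueError(f"annotation references unknown record {rid!r}")
        start, end = int(row.start), int(row.end)
        if one_based:
            start -= 1
        out[rid].append(Gene(str(row.gene_id), start, end, str(row.strand)))
    return out


def read_genome(
    fasta_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
    circular: bool = False,
) -> Genome:
    """Read a single-record FASTA plus its GFF3 (or TSV) annotation.

    Returns a :class:`Genome` with genes sorted by start and coordinates in
    the internal 0-based half-open convention.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {fasta_path}")
    if len(records) > 1:
        raise ValueError("multi-record FASTA: read one replicon per call")
    rec = records[0]
    path = str(annotation_path)
    if os.path.getsize(path) == 0 or _annotation_is_empty(path):
        logger.warning("annotation %s contains no gene lines", path)
        genes: list[Gene] = []
    elif path.endswith((".gff", ".gff3")):
        genes = _genes_from_gff3(path, {rec.id})[rec.id]
    else:
        genes = _genes_from_tsv(path, {rec.id})[rec.id]
    return Genome(rec.id, str(rec.seq), genes, circular=circular)


def _annotation_is_empty(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#") and not line.startswith("gene_id"):
                return False
    return True


def write_genome(genome: Genome, fasta_path: str | os.PathLike, gff_path: str | os.PathLike) -> None:
    SeqIO.write(
        [SeqRecord(Seq(genome.sequence), id=genome.genome_id, description="")],
        str(fasta_path),
        "fasta",
    )
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.genome_id} 1 {len(genome)}\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{genome.genome_id}\tregulonkit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_orthology(tsv_path: str | os.PathLike) -> OrthologyMap:
    """Read a 3-column orthology TSV (family_id, genome_id, gene_id)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"family_id", "genome_id", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"orthology TSV must have columns {sorted(required)}")
    df = df.drop_duplicates()
    families: dict[str, dict[str, set[str]]] = {}
    for row in df.itertuples(index=False):
        families.setdefault(row.family_id, {}).setdefault(row.genome_id, set()).add(
            row.gene_id
        )
    return OrthologyMap(families)


def write_orthology(orthology: OrthologyMap, tsv_path: str | os.PathLike) -> None:
    rows = [
        {"family_id": fam, "genome_id": genome_id, "gene_id": gene_id}
        for fam, by_genome in orthology.families.items()
        for genome_id, genes in by_genome.items()
        for gene_id in sorted(genes)
    ]
    pd.DataFrame(rows, columns=["family_id", "genome_id", "gene_id"]).to_csv(
        tsv_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Upstream extraction
# ---------------------------------------------------------------------------

DEFAULT_WINDOW = (-300, 50)


def upstream_interval(genome: Genome, gene: Gene, window: tuple[int, int] = DEFAULT_WINDOW) -> tuple[int, int]:
    """Forward-strand interval of the window (before any edge clipping)."""
    lo, hi = window
    if hi < lo:
        raise ValueError("window upper bound below lower bound")
    if gene.strand == "+":
        return gene.start + lo, gene.start + hi
    return gene.end - hi, gene.end - lo


def extract_upstream(
    genome: Genome,
    gene: Gene,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> UpstreamRegion:
    """Extract the window ``(lo, hi)`` around a gene's translation start.

    Offset 0 is the first base of the start codon; negative offsets are
    upstream in gene orientation.  Linear contigs clip the window at the
    edges (``truncated`` set); circular genomes wrap.
    """
    start, end = upstream_interval(genome, gene, window)
    n = len(genome)
    if genome.circular:
        seq = "".join(genome.sequence[i % n] for i in range(start, end))
        interval = (start % n, end % n)
        region = UpstreamRegion(gene.gene_id, genome.genome_id, interval, seq)
    else:
        cstart, cend = max(0, start), min(n, end)
        if cstart >= cend:
            return UpstreamRegion(
                gene.gene_id, genome.genome_id, (cstart, cstart), "", empty=True
            )
        seq = genome.sequence[cstart:cend]
        region = UpstreamRegion(
            gene.gene_id,
            genome.genome_id,
            (cstart, cend),
            seq,
            truncated=(cstart != start or cend != end),
        )
    if gene.strand == "-":
        region.oriented_sequence = revcomp(region.oriented_sequence)
    return region
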