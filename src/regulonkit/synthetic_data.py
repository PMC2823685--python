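"""Ground-truthed synthetic inputs for every stage of the pipeline.

A panel of annotated genomes is generated with an order-1 Markov background
at a configurable GC content (default 54%, typical of high-GC actinobacteria
like *C. glutamicum*), orthologous gene families shared across genomes, and
binding sites sampled from a planted PWM and inserted upstream of designated
regulon genes in a configurable fraction of genomes.  The regulon geometry
follows the architectures observed for the Zur regulon: a three-gene operon
with one upstream site, a three-gene operon whose lead gene shares a single
site with a divergent partner across a 29-bp gap, and a divergent gene pair
with two sites in a 118-bp gap.  Expression data are emulated as dye-swapped
two-channel spot intensities (lognormal noise, optional intensity-dependent
dye bias) and qPCR crossing points with additive noise.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import Gene, Genome, OrthologyMap, revcomp, write_genome, write_orthology
from .motif_model import BASES, MotifModel, build_motif

#: The five experimentally supported 21-bp Zur operator sites of
#: *C. glutamicum* ATCC 13032 (upstream of znuB2/cg0042, znuC2/cg0043,
#: yciC/cg0794, cg0795 and znuA1/cg2911). The cg0042 and cg0043 entries are
#: reverse complements of each other: one physical site read on both strands.
ZUR_TRAINING_SITES = [
    "TAATGATAACGGTTATCATTT",
    "AAATGATAACCGTTATCATTA",
    "TATTGAAAATGATTCCCAAAA",
    "TAATGGAAATTGTTTTCAATA",
    "TGTTGACATCCTTTTTCAATA",
]

#: Candidate site printed for the adhA (cg3107) locus; bound by the PWM scan
#: but 167 nt upstream of the mapped TSS and without expression support.
ZUR_SITE_ADHA = "AATTGAAAAACATTTCCATTA"


def default_zur_model(pseudocount: float = 0.5) -> MotifModel:
    """Palindromic PWM built from the five published Zur operator sites."""
    from .motif_model import set_threshold_from_training

    model = build_motif(ZUR_TRAINING_SITES, palindromic=True, pseudocount=pseudocount)
    return set_threshold_from_training(model)


# ---------------------------------------------------------------------------
# Background sequence
# ---------------------------------------------------------------------------

def markov_sequence(rng: np.random.Generator, length: int, gc: float = 0.54,
                    rho: float = 0.1) -> str:
    """Order-1 Markov chain with stationary composition set by GC content.

    Transition rows mix the stationary distribution with persistence ``rho``
    (a mild same-base correlation), keeping the stationary GC at ``gc``.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    T = (1 - rho) * np.tile(p, (4, 1)) + rho * np.eye(4)
    out = np.empty(length, dtype=np.int64)
    if length == 0:
        return ""
    out[0] = rng.choice(4, p=p)
    for i in range(1, length):
        out[i] = rng.choice(4, p=T[out[i - 1]])
    return "".join(BASES[i] for i in out)


def sample_site(
    rng: np.random.Generator,
    model: MotifModel,
    functional: bool = True,
    max_tries: int = 200,
) -> str:
    """Draw one W-mer column-wise from the PWM's maximum-likelihood base
    frequencies (the observed count proportions, without the scoring
    pseudocount).

    With ``functional=True`` (the default) draws are rejected until the site
    scores at or above the model's own threshold: a planted functional site
    is, by the method's definition of a candidate site, one the profile
    recognizes.  The best draw is returned if ``max_tries`` is exhausted.
    """
    f = model.counts / model.counts.sum(axis=1, keepdims=True)

    def draw() -> str:
        return "".join(BASES[rng.choice(4, p=f[k])] for k in range(model.width))

    if not functional or model.threshold is None:
        return draw()
    best, best_z = None, -np.inf
    for _ in range(max_tries):
        s = draw()
        z = model.score_value(s)
        if z >= model.threshold:
            return s
        if z > best_z:
            best, best_z = s, z
    return best  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

@dataclass
class PanelConfig:
    seed: int  # mandatory
    n_genomes: int = 10
    n_background_genes: int = 20
    gene_length: int = 600
    intergenic: int = 400
    regulon_fraction: float = 0.8
    gc: float = 0.54
    markov_rho: float = 0.1
    site_model: MotifModel | None = None  # None -> default_zur_model()
    templates: tuple[str, ...] = ("operon3_divergent", "operon3", "divergent_two_sites")
    true_fold: float = 4.0
    upstream_window: tuple[int, int] = (-300, 50)

    def __post_init__(self) -> None:
        if not 0.0 <= self.regulon_fraction <= 1.0:
            raise ValueError("regulon_fraction must be in [0, 1]")
        if self.intergenic < 80:
            raise ValueError("intergenic spacing too small for site insertion")


@dataclass
class PlantedSite:
    genome_id: str
    position: int
    strand: str
    sequence: str  # forward-strand slice


@dataclass
class GroundTruth:
    planted_sites: list[PlantedSite] = field(default_factory=list)
    regulon_members: dict[str, list[str]] = field(default_factory=dict)  # genome -> gene ids
    regulon_tus: dict[str, list[list[str]]] = field(default_factory=dict)  # genome -> TU gene lists
    expression_folds: dict[str, float] = field(default_factory=dict)  # gene -> fold
    qpcr_folds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "planted_sites": [vars(s) for s in self.planted_sites],
            "regulon_members": self.regulon_members,
            "regulon_tus": self.regulon_tus,
            "expression_folds": self.expression_folds,
            "qpcr_folds": self.qpcr_folds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


class _GenomeBuilder:
    def __init__(self, genome_id: str, rng: np.random.Generator, gc: float, rho: float):
        self.genome_id = genome_id
        self.rng = rng
        self.gc = gc
        self.rho = rho
        self.parts: list[str] = []
        self.genes: list[Gene] = []
        self.cursor = 0

    def spacer(self, length: int) -> None:
        self.parts.append(markov_sequence(self.rng, length, self.gc, self.rho))
        self.cursor += length

    def plant(self, seq: str) -> int:
        pos = self.cursor
        self.parts.append(seq)
        self.cursor += len(seq)
        return pos

    def gene(self, gene_id: str, length: int, strand: str) -> Gene:
        start = self.cursor
        self.spacer(length)
        g = Gene(gene_id, start, self.cursor, strand)
        self.genes.append(g)
        return g

    def finish(self) -> Genome:
        return Genome(self.genome_id, "".join(self.parts), self.genes)


def _emit_template(
    b: _GenomeBuilder,
    template: str,
    prefix: str,
    plant_sites: bool,
    site_seqs: list[str],
    rng: np.random.Generator,
    cfg: PanelConfig,
) -> tuple[list[str], list[list[str]], list[PlantedSite]]:
    """Append one regulon architecture to the builder.

    Returns (gene ids, TU gene lists in transcription order, planted sites).
    ``site_seqs`` supplies the site sequences in template order.
    """
    L = cfg.gene_length
    planted: list[PlantedSite] = []

    if template == "operon3":
        # site ... leadgene > gene > gene   (all '+')
        gap = int(rng.integers(30, 250))
        b.spacer(max(0, cfg.intergenic - 21 - gap))
        if plant_sites:
            pos = b.plant(site_seqs[0])
            planted.append(PlantedSite(b.genome_id, pos, "+", site_seqs[0]))
        else:
            b.spacer(21)
        b.spacer(gap)
        g1 = b.gene(f"{prefix}a", L, "+")
        b.spacer(10)
        g2 = b.gene(f"{prefix}b", L, "+")
        b.spacer(20)
        g3 = b.gene(f"{prefix}c", L, "+")
        genes = [g1.gene_id, g2.gene_id, g3.gene_id]
        return genes, [genes], planted

    if template == "operon3_divergent":
        # < gene < gene < leadgene [4 site21 4] partner >    (29-bp shared gap)
        b.spacer(cfg.intergenic)
        g1 = b.gene(f"{prefix}a", L, "-")
        b.spacer(10)
        g2 = b.gene(f"{prefix}b", L, "-")
        b.spacer(20)
        g3 = b.gene(f"{prefix}c", L, "-")
        b.spacer(4)
        if plant_sites:
            pos = b.plant(site_seqs[0])
            planted.append(PlantedSite(b.genome_id, pos, "+", site_seqs[0]))
        else:
            b.spacer(21)
        b.spacer(4)
        g4 = b.gene(f"{prefix}d", L, "+")
        genes = [g1.gene_id, g2.gene_id, g3.gene_id, g4.gene_id]
        # '-' operon transcribes right-to-left: lead is g3
        return genes, [[g3.gene_id, g2.gene_id, g1.gene_id], [g4.gene_id]], planted

    if template == "divergent_two_sites":
        # < gene [10 siteA 56 siteB 10] gene >   (118-bp gap, two sites)
        b.spacer(cfg.intergenic)
        g1 = b.gene(f"{prefix}a", L, "-")
        b.spacer(10)
        if plant_sites:
            pos = b.plant(site_seqs[0])
            planted.append(PlantedSite(b.genome_id, pos, "+", site_seqs[0]))
        else:
            b.spacer(21)
        b.spacer(56)
        if plant_sites:
            pos = b.plant(site_seqs[1])
            planted.append(PlantedSite(b.genome_id, pos, "+", site_seqs[1]))
        else:
            b.spacer(21)
        b.spacer(10)
        g2 = b.gene(f"{prefix}b", L, "+")
        genes = [g1.gene_id, g2.gene_id]
        return genes, [[g1.gene_id], [g2.gene_id]], planted

    raise ValueError(f"unknown template {template!r}")


_TEMPLATE_N_SITES = {"operon3": 1, "operon3_divergent": 1, "divergent_two_sites": 2}


def simulate_panel(config: PanelConfig) -> tuple[dict[str, Genome], OrthologyMap, GroundTruth]:
    """Generate a genome panel with planted regulon sites and full ground truth.

    Deterministic for a fixed config (including seed).  The first
    ``round(regulon_fraction * n_genomes)`` genomes carry planted sites; all
    genomes carry the orthologous genes.
    """
    rng = np.random.default_rng(config.seed)
    model = config.site_model or default_zur_model()
    n_carriers = int(round(config.regulon_fraction * config.n_genomes))

    truth = GroundTruth()
    genomes: dict[str, Genome] = {}
    families: dict[str, dict[str, set[str]]] = {}

    for gi in range(config.n_genomes):
        genome_id = f"genome{gi:02d}"
        carries = gi < n_carriers
        b = _GenomeBuilder(genome_id, rng, config.gc, config.markov_rho)
        b.spacer(150)

        members: list[str] = []
        tus: list[list[str]] = []
        for ti, template in enumerate(config.templates):
            site_seqs = [sample_site(rng, model) for _ in range(_TEMPLATE_N_SITES[template])]
            genes, tu_lists, planted = _emit_template(
                b, template, f"g{gi:02d}_t{ti}_", carries, site_seqs, rng, config
            )
            for slot, gene_id in enumerate(genes):
                families.setdefault(f"FAM_t{ti}_{slot}", {}).setdefault(genome_id, set()).add(gene_id)
            if carries:
                truth.planted_sites.extend(planted)
                members.extend(genes)
                tus.extend(tu_lists)

        for bi in range(config.n_background_genes):
            b.spacer(config.intergenic)
            g = b.gene(f"g{gi:02d}_bg{bi:02d}", config.gene_length, "+" if bi % 2 == 0 else "-")
            families.setdefault(f"FAM_bg{bi:02d}", {}).setdefault(genome_id, set()).add(g.gene_id)
        b.spacer(150)

        genomes[genome_id] = b.finish()
        truth.regulon_members[genome_id] = members
        truth.regulon_tus[genome_id] = tus
        for gene_id in members:
            truth.expression_folds[gene_id] = config.true_fold
            truth.qpcr_folds[gene_id] = config.true_fold

    # self-consistency: recorded site sequences must equal the genomic slices
    for s in truth.planted_sites:
        piece = genomes[s.genome_id].sequence[s.position : s.position + len(s.sequence)]
        assert piece == s.sequence, "planted site does not match genomic slice"

    return genomes, OrthologyMap(families), truth


def table1_layout(seed: int = 0, gc: float = 0.54) -> tuple[Genome, GroundTruth]:
    """Single genome reproducing the published *C. glutamicum* Zur geometry.

    Nine genes in five transcription units: the cg0040-cg0041-cg0042 operon
    sharing one site with divergent cg0043 across a 29-bp gap, divergent
    cg0794/cg0795 with two sites in a 118-bp gap, and the cg2911-cg2912-cg2913
    operon with one upstream site.  The five published 21-mers are planted.
    """
    rng = np.random.default_rng(seed)
    b = _GenomeBuilder("cgl_fixture", rng, gc, 0.1)
    truth = GroundTruth()
    L = 600

    def plant(seq: str) -> None:
        pos = b.plant(seq)
        truth.planted_sites.append(PlantedSite(b.genome_id, pos, "+", seq))

    b.spacer(400)
    # cg0040 < cg0041 < cg0042   [4 | site | 4]   cg0043 >
    b.gene("cg0040", L, "-")
    b.spacer(10)
    b.gene("cg0041", L, "-")
    b.spacer(20)
    b.gene("cg0042", L, "-")
    b.spacer(4)
    plant(ZUR_TRAINING_SITES[0])  # read on '-' gives the cg0043 motif
    b.spacer(4)
    b.gene("cg0043", L, "+")

    b.spacer(400)
    # cg0794 < [10 | site | 56 | site | 10] cg0795 >
    b.gene("cg0794", L, "-")
    b.spacer(10)
    plant(ZUR_TRAINING_SITES[2])
    b.spacer(56)
    plant(ZUR_TRAINING_SITES[3])
    b.spacer(10)
    b.gene("cg0795", L, "+")

    b.spacer(400)
    # site [40] cg2911 > cg2912 > cg2913 >
    plant(ZUR_TRAINING_SITES[4])
    b.spacer(40)
    b.gene("cg2911", L, "+")
    b.spacer(10)
    b.gene("cg2912", L, "+")
    b.spacer(20)
    b.gene("cg2913", L, "+")
    b.spacer(400)

    genome = b.finish()
    truth.regulon_members[genome.genome_id] = [g.gene_id for g in genome.genes]
    truth.regulon_tus[genome.genome_id] = [
        ["cg0042", "cg0041", "cg0040"],
        ["cg0043"],
        ["cg0794"],
        ["cg0795"],
        ["cg2911", "cg2912", "cg2913"],
    ]
    for g in genome.genes:
        truth.expression_folds[g.gene_id] = 4.0
        truth.qpcr_folds[g.gene_id] = 4.0
    for s in truth.planted_sites:
        assert genome.sequence[s.position : s.position + 21] == s.sequence
    return genome, truth


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_microarray(
    folds: dict[str, float],
    n_spots: int = 4,
    n_arrays: int = 2,
    noise_sd: float = 0.25,
    dye_bias_fn=None,
    base_log2_intensity: tuple[float, float] = (8.0, 14.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Dye-swapped two-channel spot intensities around true fold changes.

    Each gene gets ``n_spots`` spots on each of ``n_arrays`` arrays; arrays
    alternate dye orientation (label swapping).  Per spot,
    m = log2(fold) + e + s*bias(a) with e ~ N(0, noise_sd) and s = +1/-1 by
    dye orientation, and the two channel intensities are reconstructed from
    (m, a).  All folds must be positive.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene_id, fold in folds.items():
        if fold <= 0:
            raise ValueError(f"gene {gene_id}: fold must be positive")
        m_true = np.log2(fold)
        for ai in range(n_arrays):
            orientation = "test=Cy5" if ai % 2 == 0 else "test=Cy3"
            sign = 1.0 if orientation == "test=Cy5" else -1.0
            for _ in range(n_spots):
                a = rng.uniform(*base_log2_intensity)
                bias = sign * dye_bias_fn(a) if dye_bias_fn is not None else 0.0
                m = m_true + rng.normal(0.0, noise_sd) + bias if noise_sd > 0 else m_true + bias
                rows.append({
                    "gene_id": gene_id,
                    "array_id": f"array{ai}",
                    "dye_orientation": orientation,
                    "intensity_test": 2.0 ** (a + m / 2),
                    "intensity_ref": 2.0 ** (a - m / 2),
                })
    return pd.DataFrame(rows)


def simulate_rtpcr(
    folds: dict[str, float],
    replicates: int = 2,
    cp_noise_sd: float = 0.2,
    cp_control_base: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR crossing points: CP_test = CP_control - log2(fold) + noise.

    Long table (gene_id, condition, cp) with ``replicates`` technical
    replicates per condition.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene_id, fold in folds.items():
        if fold <= 0:
            raise ValueError(f"gene {gene_id}: fold must be positive")
        for _ in range(replicates):
            rows.append({
                "gene_id": gene_id,
                "condition": "control",
                "cp": cp_control_base + rng.normal(0.0, cp_noise_sd),
            })
        for _ in range(replicates):
            rows.append({
                "gene_id": gene_id,
                "condition": "test",
                "cp": cp_control_base - np.log2(fold) + rng.normal(0.0, cp_noise_sd),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def write_panel(
    out_dir: str | os.PathLike,
    genomes: dict[str, Genome],
    orthology: OrthologyMap,
    truth: GroundTruth,
) -> None:
    """Write FASTA + GFF3 per genome, the orthology TSV, and the truth JSON."""
    os.makedirs(out_dir, exist_ok=True)
    for genome_id, genome in genomes.items():
        write_genome(
            genome,
            os.path.join(out_dir, f"{genome_id}.fasta"),
            os.path.join(out_dir, f"{genome_id}.gff3"),
        )
    write_orthology(orthology, os.path.join(out_dir, "orthology.tsv"))
    truth.to_json(os.path.join(out_dir, "truth.json"))
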