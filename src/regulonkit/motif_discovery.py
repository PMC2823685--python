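"""Shared-motif discovery across a set of upstream regions.

A one-occurrence-per-sequence search in the expectation-maximization family,
built for strong palindromic motifs shared by most input regions:

1. *Seeding* (per restart): one region is chosen at random and every one of
   its windows is tried as a single-site seed model (palindrome-symmetrized);
   the seed that maximizes the summed best-window score across all regions
   supplies the restart's initial window assignment.  Enumerated seeding is
   what rescues the search from the local optima that plague random starts.
2. *Refinement*: regions are revisited in turn; the held-out region's best
   window (either strand) under the model built from the other regions'
   windows is proposed, and the move is accepted only if the objective — the
   total information content of the model rebuilt from all chosen windows —
   does not decrease.  This makes the objective non-decreasing within a
   restart and guarantees termination.
3. The restart with the highest objective wins.  After convergence a region
   is reported siteless when its window scores far below the rest of the
   training set (under the leave-one-out model), as long as a minimum
   fraction of regions keeps a site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import UpstreamRegion, revcomp
from .motif_model import (
    COMPLEMENT_INDEX,
    MotifModel,
    build_motif,
    encode,
    set_threshold_from_training,
    weights_from_counts,
)


@dataclass
class DiscoveryConfig:
    width: int = 21
    palindromic: bool = True
    restarts: int = 5
    max_iterations: int = 50
    seed: int = 13
    min_regions_with_site: float = 0.5
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.palindromic and self.width % 2 == 0:
            raise ValueError(
                "palindromic motifs use an odd width (palindrome with a "
                "1-bp non-palindromic centre)"
            )


@dataclass
class DiscoveredSite:
    """Best window chosen for one region during discovery.

    ``offset`` is 0-based within the oriented region sequence; ``strand`` is
    '+' if the motif matches the region sequence as written, '-' if it
    matches the reverse complement.
    """

    region_index: int
    gene_id: str
    offset: int
    strand: str
    sequence: str
    z: float


def _strand_scores(weights: np.ndarray, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(forward, reverse) window scores along one encoded sequence."""
    from .regulon_scan import _window_scores

    rc_weights = weights[::-1, :][:, COMPLEMENT_INDEX]
    return _window_scores(weights, codes), _window_scores(rc_weights, codes)


def _best_window(weights: np.ndarray, codes: np.ndarray) -> tuple[int, str, float]:
    """Best-scoring window over both strands; ties -> leftmost, '+' first."""
    fwd, rev = _strand_scores(weights, codes)
    i_f, i_r = int(np.argmax(fwd)), int(np.argmax(rev))
    if fwd[i_f] > rev[i_r]:
        return i_f, "+", float(fwd[i_f])
    if rev[i_r] > fwd[i_f]:
        return i_r, "-", float(rev[i_r])
    return (i_f, "+", float(fwd[i_f])) if i_f <= i_r else (i_r, "-", float(rev[i_r]))


def _window_seq(seq: str, offset: int, strand: str, width: int) -> str:
    w = seq[offset : offset + width]
    return w if strand == "+" else revcomp(w)


def discover_motif(
    regions: list[UpstreamRegion],
    config: DiscoveryConfig | None = None,
) -> tuple[MotifModel, list[DiscoveredSite]]:
    """Find one shared motif across upstream regions.

    Returns the best model over all restarts plus one best site per reported
    region.  Deterministic for a fixed seed and input order.
    """
    config = config or DiscoveryConfig()
    W = config.width
    keep_idx = [i for i, r in enumerate(regions) if len(r.oriented_sequence) >= W]
    if len(keep_idx) < 3:
        raise ValueError("need at least 3 regions no shorter than the motif width")
    regions = [regions[i] for i in keep_idx]
    seqs = [r.oriented_sequence for r in regions]
    codes = [encode(s) for s in seqs]
    n = len(seqs)
    rng = np.random.default_rng(config.seed)

    def model_weights(windows: list[str]) -> np.ndarray:
        m = build_motif(windows, palindromic=config.palindromic,
                        pseudocount=config.pseudocount)
        return m.weights

    def objective(windows: list[str]) -> float:
        m = build_motif(windows, palindromic=config.palindromic,
                        pseudocount=config.pseudocount)
        return float(m.information_content().sum())

    best_obj = -np.inf
    best_state: list[tuple[int, str]] | None = None

    for restart in range(config.restarts):
        seed_region = int(rng.integers(0, n))
        # enumerate every window of the seed region as a single-site seed
        best_seed_score = -np.inf
        state: list[tuple[int, str]] = [(0, "+")] * n
        for off in range(len(seqs[seed_region]) - W + 1):
            window = seqs[seed_region][off : off + W]
            if "N" in window:
                continue
            w = model_weights([window, window])  # >=2 sites required; duplicate
            total = 0.0
            assignment: list[tuple[int, str]] = []
            for j in range(n):
                o, st, z = _best_window(w, codes[j])
                assignment.append((o, st))
                total += z
            if total > best_seed_score:
                best_seed_score = total
                state = assignment

        windows = [_window_seq(seqs[i], *state[i], W) for i in range(n)]
        obj = objective(windows)
        for _ in range(config.max_iterations):
            moved = False
            for i in range(n):
                others = [windows[j] for j in range(n) if j != i]
                off, st, _ = _best_window(model_weights(others), codes[i])
                if (off, st) == state[i]:
                    continue
                trial = list(windows)
                trial[i] = _window_seq(seqs[i], off, st, W)
                trial_obj = objective(trial)
                # strict improvement only: keeps the objective monotone and
                # rules out cycling through equal-objective assignments
                if trial_obj > obj + 1e-12:
                    state[i] = (off, st)
                    windows = trial
                    obj = trial_obj
                    moved = True
            if not moved:
                break
        if obj > best_obj:
            best_obj = obj
            best_state = list(state)

    assert best_state is not None
    windows = [_window_seq(seqs[i], *best_state[i], W) for i in range(n)]

    # zero-or-one occurrence per region: report a region siteless when its
    # window scores below half the training minimum of the model built from
    # the other windows (weakest first, while enough regions keep a site)
    kept = list(range(n))
    min_keep = max(2, int(np.ceil(config.min_regions_with_site * n)))
    full = build_motif(windows, palindromic=config.palindromic,
                       pseudocount=config.pseudocount)
    for i in sorted(range(n), key=lambda i: full.score_value(windows[i])):
        if len(kept) <= min_keep:
            break
        others = [windows[j] for j in kept if j != i]
        loo = build_motif(others, palindromic=config.palindromic,
                          pseudocount=config.pseudocount)
        loo_min = min(loo.score_value(w) for w in others)
        if loo_min > 0 and loo.score_value(windows[i]) < 0.5 * loo_min:
            kept.remove(i)

    model = build_motif([windows[i] for i in kept],
                        palindromic=config.palindromic,
                        pseudocount=config.pseudocount)
    set_threshold_from_training(model)

    sites = [
        DiscoveredSite(
            region_index=keep_idx[i],
            gene_id=regions[i].gene_id,
            offset=best_state[i][0],
            strand=best_state[i][1],
            sequence=windows[i],
            z=model.score_value(windows[i]),
        )
        for i in kept
    ]
    return model, sites
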