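"""Synthetic inputs with the statistical structure the analyses assume.

Every stage of the pipeline can be exercised without any external data:

* :func:`simulate_alignment` — forward simulation of characters along a
  tree under a reversible substitution model with discrete-gamma rates;
* :func:`simulate_missingness` / :func:`simulate_occupancy_matrix` —
  per-locus taxon-presence patterns spanning a target occupancy range,
  emulating the patchy supermatrices of target-capture studies;
* :func:`simulate_trace` — stationary AR(1) posterior log-likelihood
  traces standing in for MCMC output;
* :func:`simulate_site_lnl` — per-site log-likelihood matrices with
  controlled between-tree effect sizes for RELL/AU experiments;
* :func:`make_bait_fixture` — a hand-enumerable toy bait-design input set
  placing candidates on both sides of every filtering threshold.

All generators are pure functions of their arguments and a seed; a single
run seed can be fanned out to per-generator child seeds with
:func:`child_seed` (CRC-32 of a label mixed into a NumPy SeedSequence), so
stages are reproducible in isolation and jointly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .alphabets import AMINO_ACID, Alphabet
from .bait_design import HitRecord
from .bayes_factors import MCMCTrace
from .phylo_likelihood import SubstitutionModel, transition_probabilities
from .seqio import Alignment, PartitionMap, PhyloTree, SiteLnLMatrix, TreeNode


def child_seed(seed: int, label: str) -> np.random.SeedSequence:
    """Deterministic per-purpose child seed derived from a run seed."""
    return np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    seed=None,
) -> Alignment:
    """Evolve characters along the tree from the stationary distribution.

    Root states are drawn from the model's equilibrium frequencies; each
    site is assigned a gamma rate category, and states propagate along
    every branch through the corresponding transition matrix.  Leaf rows
    come back in the tree's postorder leaf order.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _rng(seed)
    k = model.k
    rates, weights = model.category_rates()
    cats = rng.choice(len(rates), size=n_sites, p=weights)
    root_states = rng.choice(k, size=n_sites, p=model.frequencies)

    leaf_states: dict[str, np.ndarray] = {}

    def walk(node: TreeNode, states: np.ndarray) -> None:
        if node.is_leaf:
            leaf_states[node.label] = states
            return
        for child in node.children:
            child_states = np.empty(n_sites, dtype=np.int64)
            for ci, rate in enumerate(rates):
                mask = cats == ci
                if not mask.any():
                    continue
                p = transition_probabilities(model, child.length, rate)
                cum = np.cumsum(p, axis=1)
                u = rng.random(int(mask.sum()))
                child_states[mask] = np.minimum(
                    (u[:, None] > cum[states[mask]]).sum(axis=1), k - 1
                )
            walk(child, child_states)

    walk(tree.root, root_states)
    symbols = np.array(list(model.alphabet.states))
    taxa = [n.label for n in tree.root.postorder() if n.is_leaf]
    data = np.vstack([symbols[leaf_states[t]] for t in taxa])
    return Alignment(taxa, data, model.alphabet)


# ---------------------------------------------------------------------------
# Missingness / occupancy
# ---------------------------------------------------------------------------

def simulate_missingness(
    loci_lengths: list[int],
    n_taxa: int,
    occupancy_range: tuple[int, int],
    seed=None,
) -> list[np.ndarray]:
    """Per-locus boolean taxon masks (True = present).

    Each locus draws its occupancy uniformly within ``occupancy_range``
    and retains that many taxa, chosen uniformly without replacement.
    """
    lo, hi = occupancy_range
    if not 1 <= lo <= hi <= n_taxa:
        raise ValueError(f"occupancy range ({lo}, {hi}) outside [1, {n_taxa}]")
    rng = _rng(seed)
    masks = []
    for _ in loci_lengths:
        occupancy = int(rng.integers(lo, hi + 1))
        present = rng.choice(n_taxa, size=occupancy, replace=False)
        mask = np.zeros(n_taxa, dtype=bool)
        mask[present] = True
        masks.append(mask)
    return masks


def simulate_occupancy_matrix(
    n_loci: int = 134,
    n_taxa: int = 44,
    length_range: tuple[int, int] = (56, 363),
    occupancy_range: tuple[int, int] = (5, 36),
    alphabet: Alphabet = AMINO_ACID,
    seed=None,
) -> list[Alignment]:
    """Per-locus alignments with target-capture-style patchiness.

    Defaults reproduce the shape of a 134-locus, 44-taxon capture matrix
    with locus lengths spanning 56-363 columns and per-locus occupancy
    between 5 and 36 taxa.  Residues are i.i.d. draws over the alphabet;
    this emulates the bookkeeping structure (lengths, occupancy), not the
    phylogenetic signal.
    """
    rng = _rng(seed)
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_loci)
    masks = simulate_missingness(list(lengths), n_taxa, occupancy_range, rng)
    taxa = [f"taxon{i + 1:02d}" for i in range(n_taxa)]
    symbols = np.array(list(alphabet.states))
    loci = []
    for li, (length, mask) in enumerate(zip(lengths, masks)):
        present = [t for t, keep in zip(taxa, mask) if keep]
        data = symbols[rng.integers(0, alphabet.k, size=(len(present), int(length)))]
        loci.append(
            Alignment(
                present,
                data,
                alphabet,
                partitions=PartitionMap(((f"locus{li + 1:03d}", 1, int(length)),)),
            )
        )
    return loci


# ---------------------------------------------------------------------------
# MCMC traces and site-lnL matrices
# ---------------------------------------------------------------------------

def simulate_trace(
    n_cycles: int,
    mean: float,
    sd: float,
    rho: float,
    seed=None,
    chain_id: str = "chain1",
) -> MCMCTrace:
    """Stationary AR(1) log-likelihood trace:
    x_i = mean + rho*(x_{i-1} - mean) + eps,  eps ~ N(0, sd^2 * (1 - rho^2)),
    x_0 ~ N(mean, sd^2), so every sample is marginally N(mean, sd^2)."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    rng = _rng(seed)
    innovations = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n_cycles)
    x = np.empty(n_cycles)
    x[0] = rng.normal(mean, sd)
    for i in range(1, n_cycles):
        x[i] = mean + rho * (x[i - 1] - mean) + innovations[i]
    return MCMCTrace(chain_id=chain_id, cycles=np.arange(n_cycles), lnl=x)


def write_trace(trace: MCMCTrace, path, lnl_column: str = "lnL") -> None:
    """Write a trace in the tabular dialect :func:`bayes_factors.read_trace`
    accepts (header row, tab-separated, one sample per row)."""
    with open(path, "w") as fh:
        fh.write(f"cycle\t{lnl_column}\n")
        for cyc, v in zip(trace.cycles, trace.lnl):
            fh.write(f"{cyc}\t{v:.17g}\n")


def simulate_site_lnl(
    n_trees: int,
    n_sites: int,
    tree_offsets,
    site_sd: float,
    seed=None,
) -> SiteLnLMatrix:
    """Controlled-effect per-site lnL matrix for resampling experiments.

    Site i under tree j gets  base_i + offset_j + noise_ij  with
    base_i ~ N(-3, 1) truncated at 0 from above and noise ~ N(0, site_sd^2);
    the result is clipped at 0 so the discrete-data lnL <= 0 invariant
    holds (a modelling convenience, not a claim about real data).
    """
    offsets = np.asarray(tree_offsets, dtype=float)
    if offsets.shape != (n_trees,):
        raise ValueError(f"need {n_trees} tree offsets, got shape {offsets.shape}")
    if site_sd <= 0:
        raise ValueError("site_sd must be positive")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _rng(seed)
    base = truncnorm.rvs(-np.inf, 3.0, loc=-3.0, scale=1.0, size=n_sites,
                         random_state=rng)
    noise = rng.normal(0.0, site_sd, size=(n_trees, n_sites))
    values = np.minimum(base[None, :] + offsets[:, None] + noise, 0.0)
    ids = [f"T{j}" for j in range(n_trees)]
    return SiteLnLMatrix(ids, values)


# ---------------------------------------------------------------------------
# Bait-design fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaitFixture:
    """Toy bait-design inputs plus the hand-enumerated expected decisions."""

    sequences: dict[str, str]
    hits: list[HitRecord]
    expected_status: dict[str, str]

    def write(self, directory) -> tuple[str, str, str]:
        """Write masked FASTA, hit-table TSV and expectation TSV; byte
        deterministic.  Returns the three file paths."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        fasta = d / "bait_sources.fasta"
        with open(fasta, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n{seq}\n")
        table = d / "bait_hits.tsv"
        with open(table, "w") as fh:
            for h in self.hits:
                tm = "" if h.tm is None else f"{h.tm:g}"
                fh.write(f"{h.bait_id}\t{h.target_id}\t{h.length}\t{h.identity:g}\t{tm}\n")
        expected = d / "bait_expected.tsv"
        with open(expected, "w") as fh:
            for bait_id, status in self.expected_status.items():
                fh.write(f"{bait_id}\t{status}\n")
        return str(fasta), str(table), str(expected)


def make_bait_fixture(seed: int = 0) -> BaitFixture:
    """Deterministic toy inputs exercising every bait-design rule.

    Contains an N-run of exactly 10 (replaced), a run of 11 (kept, so the
    bait is rejected as ambiguous), a 100-bp fragment (padded), a clean
    220-bp sequence (exactly 3 tiles), and a heavily soft-masked span;
    hit records sit on both sides of the length-45 / identity-75 strict
    bounds and the 10-hit mid-bin / 2-hit high-bin Tm limits.
    """
    rng = _rng(int(seed))
    bases = np.array(list("ACGT"))

    def random_seq(n: int) -> str:
        return "".join(bases[rng.integers(0, 4, size=n)])

    sequences = {
        # 120 bp with an interior N-run of exactly 10 -> T-replaced, 1 clean bait
        "nrun10": random_seq(55) + "N" * 10 + random_seq(55),
        # 120 bp with an N-run of 11 -> Ns survive cleaning, bait ambiguous
        "nrun11": random_seq(54) + "N" * 11 + random_seq(55),
        # 100 bp fragment -> padded with 20 T, 1 bait
        "short100": random_seq(100),
        # 220 bp clean -> tiles at 0, 50, 100
        "clean220": random_seq(220),
        # 120 bp with 40 soft-masked (lowercase) bases -> masked fraction 1/3
        "masked40": random_seq(40) + random_seq(40).lower() + random_seq(40),
    }

    hits: list[HitRecord] = [
        # short100_b1: boundary hits on the length/identity bounds; only the
        # strictly-passing one survives, leaving a single mid-bin hit.
        HitRecord("short100_b1", "genomeA", 45, 99.0, 63.0),  # length bound: dropped
        HitRecord("short100_b1", "genomeA", 46, 75.0, 63.0),  # identity bound: dropped
        HitRecord("short100_b1", "genomeB", 46, 76.0, 63.0),  # retained
    ]
    # clean220_b1: exactly 10 mid-bin + 2 high-bin hits -> still retained
    hits += [HitRecord("clean220_b1", f"g{i}", 120, 95.0, 63.0) for i in range(10)]
    hits += [HitRecord("clean220_b1", f"h{i}", 120, 98.0, 66.0) for i in range(2)]
    # clean220_b2: 11 mid-bin hits -> rejected:mid-bin
    hits += [HitRecord("clean220_b2", f"g{i}", 120, 95.0, 63.0) for i in range(11)]
    # clean220_b3: 3 hits above 65 degC -> rejected:high-bin
    hits += [HitRecord("clean220_b3", f"h{i}", 120, 99.0, 70.0) for i in range(3)]

    expected_status = {
        "nrun10_b1": "retained",
        "nrun11_b1": "rejected:ambiguous",
        "short100_b1": "retained",
        "clean220_b1": "retained",
        "clean220_b2": "rejected:mid-bin",
        "clean220_b3": "rejected:high-bin",
        "masked40_b1": "rejected:masked",
    }
    return BaitFixture(sequences=sequences, hits=hits, expected_status=expected_status)


__all__ = [
    "child_seed",
    "simulate_alignment",
    "simulate_missingness",
    "simulate_occupancy_matrix",
    "simulate_trace",
    "write_trace",
    "simulate_site_lnl",
    "BaitFixture",
    "make_bait_fixture",
]
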