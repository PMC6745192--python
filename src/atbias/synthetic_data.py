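"""Generators for every input the pipeline consumes.

Each generator emulates the statistical structure the analyses assume:

* :func:`simulate_alignment` — sequence evolution along a guide tree under
  HKY with *branch-specific* equilibrium frequencies, the minimal
  nonhomogeneous model that produces compositional convergence. The
  default scenario evolves two phylogenetically distant lineages toward
  ~88% AT at 20x the background rate.
* :func:`simulate_depth` — depth falling log-linearly from ~3,000x in the
  least AT-rich windows to ~17x in the most AT-rich, with per-position
  negative-binomial noise, and insert sizes shrinking from ~300 to
  ~200 bp as AT rises.
* :func:`simulate_genome` — a genome with coding/intergenic AT contrast
  and a feature table (defaults: 78.5% coding, coding AT 0.881,
  intergenic AT 0.938).
* :func:`simulate_kmer_histogram` — a k-mer spectrum with an error peak
  at low multiplicity and a genome peak near the target coverage.

Every generator takes an explicit seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
from scipy.linalg import expm

from .composition import windowed_at
from .types import (BaseComposition, DepthTrack, Feature, FeatureTable,
                    InsertTrack, KmerHistogram, MultipleAlignment,
                    SequenceRecord, TaxonGroups)

__all__ = [
    "BranchModel", "EvolutionScenario", "CoverageScenario",
    "simulate_alignment", "simulate_depth", "simulate_genome",
    "simulate_kmer_histogram", "default_convergence_scenario",
]

_BASES = np.array([b"A", b"C", b"G", b"T"])


@dataclass(frozen=True)
class BranchModel:
    """HKY parameters acting along one branch."""

    freqs: BaseComposition
    kappa: float = 2.0
    rate: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.rate <= 0:
            raise ValueError("rate multiplier must be positive")


@dataclass(frozen=True)
class EvolutionScenario:
    """A guide tree plus per-branch substitution models.

    ``branch_models`` overrides the default model on the terminal branch
    of the named leaf (or the branch above the internal node with that
    label). The root sequence is drawn from ``root_freqs``.
    """

    newick: str
    length: int
    seed: int
    root_freqs: BaseComposition
    default_model: BranchModel
    branch_models: Mapping[str, BranchModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("sequence length must be >= 1")
        if self.seed is None:
            raise ValueError("an explicit seed is mandatory")


def _hky_rate_matrix(freqs: np.ndarray, kappa: float) -> np.ndarray:
    """HKY85 generator normalized to one expected substitution per unit time."""
    # base order A, C, G, T; transitions are A<->G and C<->T
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transition = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))
            Q[i, j] = (kappa if transition else 1.0) * freqs[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(freqs, np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate frequencies: no substitution process")
    return Q / scale


def _evolve(parent: np.ndarray, P: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Draw child states per site from transition matrix rows."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent.shape[0])
    return (u[:, None] > cum[parent]).sum(axis=1).astype(np.int8)


def simulate_alignment(
        scenario: EvolutionScenario) -> tuple[MultipleAlignment, dendropy.Tree]:
    """Evolve sequences along the guide tree; returns alignment + true tree.

    Sites are independent; each branch applies expm(Q * t * rate) with its
    own HKY model, so equilibrium composition can change per branch
    (nonhomogeneous evolution). The guide tree must be binary; leaf labels
    become alignment taxa. Byte-identical output for identical seeds.
    """
    tree = dendropy.Tree.get(data=scenario.newick, schema="newick",
                             preserve_underscores=True)
    rng = np.random.default_rng(scenario.seed)
    for node in tree.preorder_node_iter():
        n_children = len(node.child_nodes())
        if node is tree.seed_node:
            if n_children not in (2, 3):
                raise ValueError("guide tree root must have 2 or 3 children")
        elif n_children not in (0, 2):
            raise ValueError(
                "guide tree must be binary (every internal node has "
                f"exactly 2 children; found one with {n_children})")
    root_p = scenario.root_freqs.as_array()
    root_seq = rng.choice(4, size=scenario.length, p=root_p).astype(np.int8)
    tree.seed_node.state = root_seq
    taxa: list[str] = []
    rows: list[str] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        label = (node.taxon.label if node.taxon is not None
                 else node.label)
        model = scenario.branch_models.get(label, scenario.default_model) \
            if label is not None else scenario.default_model
        t = node.edge.length or 0.0
        if t < 0:
            raise ValueError("guide tree branch lengths must be >= 0")
        if t == 0:
            node.state = node.parent_node.state.copy()
        else:
            Q = _hky_rate_matrix(model.freqs.as_array(), model.kappa)
            P = expm(Q * t * model.rate)
            # guard tiny negative entries from the matrix exponential
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            node.state = _evolve(node.parent_node.state, P, rng)
        if node.is_leaf():
            taxa.append(node.taxon.label)
            rows.append("".join(_BASES[node.state].astype(str)))
    return MultipleAlignment(taxa, rows), tree


def default_convergence_scenario(
        seed: int, length: int = 1200, n_background: int = 7,
        focal: str = "focal_plant", attractor: str = "atrich_protist",
        at_shifted: float = 0.88, at_background: float = 0.434,
        rate_multiplier: float = 20.0,
) -> tuple[EvolutionScenario, TaxonGroups]:
    """Two-clade scenario with two distant lineages drifting to high AT.

    Clade sizes, compositions and the rate multiplier default to the
    study conditions: background AT ~43.4% (typical of autotrophic-plant
    rRNA genes), focal lineages at AT 0.88 evolving 20x faster. The focal
    taxon belongs to the plant-like clade; the attractor sits inside the
    protist-like clade. Group labels are "plants" and "protists".
    """
    if n_background < 2:
        raise ValueError("need at least 2 background taxa per clade")

    def ladder(names: list[str], tip: float, internal: float) -> str:
        sub = f"({names[0]}:{tip},{names[1]}:{tip})"
        for name in names[2:]:
            sub = f"({sub}:{internal},{name}:{tip})"
        return sub

    plants = [focal] + [f"plant_{i}" for i in range(1, n_background + 1)]
    protists = [attractor] + [f"protist_{i}"
                              for i in range(1, n_background + 1)]
    newick = (f"({ladder(plants, 0.08, 0.05)}:0.10,"
              f"{ladder(protists, 0.08, 0.05)}:0.10);")
    shifted = BranchModel(
        freqs=BaseComposition.from_alpha(at_shifted),
        kappa=2.0, rate=rate_multiplier)
    scenario = EvolutionScenario(
        newick=newick,
        length=length,
        seed=seed,
        root_freqs=BaseComposition.from_alpha(at_background),
        default_model=BranchModel(
            freqs=BaseComposition.from_alpha(at_background), kappa=2.0),
        branch_models={focal: shifted, attractor: shifted},
    )
    groups = TaxonGroups({**{t: "plants" for t in plants},
                          **{t: "protists" for t in protists}})
    return scenario, groups


@dataclass(frozen=True)
class CoverageScenario:
    """Depth/insert model parameters for :func:`simulate_depth`.

    Window mean depth decays log-linearly in window AT content from
    ``max_depth`` at the least AT-rich window to ``min_depth`` at the most
    AT-rich. ``dispersion`` is the negative-binomial overdispersion (the
    variance is mean + dispersion * mean^2); 0 gives deterministic depth.
    Insert size falls linearly from ``insert_at_low_at`` to
    ``insert_at_high_at`` over the same AT range.
    """

    max_depth: float = 3000.0
    min_depth: float = 17.0
    dispersion: float = 0.1
    insert_at_low_at: float = 300.0
    insert_at_high_at: float = 200.0
    insert_sd: float = 15.0
    pairs_per_window: int = 25
    window: int = 200

    def __post_init__(self) -> None:
        if not self.max_depth >= self.min_depth > 0:
            raise ValueError("require max_depth >= min_depth > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if min(self.insert_at_low_at, self.insert_at_high_at) <= 0:
            raise ValueError("insert sizes must be positive")


def _window_mean_depths(at: np.ndarray,
                        scenario: CoverageScenario) -> np.ndarray:
    """Log-linear AT->depth curve hitting both endpoints exactly."""
    at_min, at_max = float(at.min()), float(at.max())
    if at_max == at_min:
        raise ValueError(
            "window AT content is constant; the AT-depth relationship is "
            "undefined for a compositionally homogeneous genome")
    u = (at - at_min) / (at_max - at_min)
    lam = np.log(scenario.max_depth / scenario.min_depth)
    return scenario.max_depth * np.exp(-lam * u)


def simulate_depth(scenario: CoverageScenario,
                   seq: SequenceRecord,
                   seed: int) -> tuple[DepthTrack, InsertTrack]:
    """Depth and insert tracks with AT-dependent dropout.

    Per-position depths are negative-binomial around the window mean
    (Poisson-like at ``dispersion`` 0+; exactly the rounded mean at 0).
    Insert sizes are normal around a linear-in-AT mean, assigned to pair
    midpoints uniform within each window. The trailing partial window
    gets the depth of the last full window.
    """
    rng = np.random.default_rng(seed)
    profile = windowed_at(seq, window=scenario.window)
    at = profile["at_fraction"].to_numpy()
    if np.isnan(at).any():
        raise ValueError("a window has no unambiguous bases")
    means = _window_mean_depths(at, scenario)
    n_win = len(means)
    w = scenario.window
    depths = np.empty(len(seq), dtype=np.int64)
    for i, mu in enumerate(means):
        sl = slice(i * w, (i + 1) * w)
        if scenario.dispersion == 0:
            depths[sl] = int(round(mu))
        else:
            # NB with mean mu, variance mu + dispersion * mu^2
            r = 1.0 / scenario.dispersion
            p = r / (r + mu)
            depths[sl] = rng.negative_binomial(r, p, size=w)
    if n_win * w < len(seq):
        depths[n_win * w:] = depths[n_win * w - 1]
    at_min, at_max = float(at.min()), float(at.max())
    slope = ((scenario.insert_at_high_at - scenario.insert_at_low_at)
             / (at_max - at_min))
    midpoints, sizes = [], []
    for i, a in enumerate(at):
        mean_insert = scenario.insert_at_low_at + slope * (a - at_min)
        m = scenario.pairs_per_window
        midpoints.append(i * w + rng.random(m) * w)
        draw = rng.normal(mean_insert, scenario.insert_sd, size=m)
        sizes.append(np.clip(draw, 1.0, None))
    inserts = InsertTrack(reference=seq.id,
                          midpoints=np.concatenate(midpoints),
                          sizes=np.concatenate(sizes))
    return DepthTrack(reference=seq.id, depths=depths), inserts


def _random_bases(n: int, at: float, rng: np.random.Generator) -> str:
    p = BaseComposition.from_alpha(at).as_array()
    idx = rng.choice(4, size=n, p=p)
    return "".join(_BASES[idx].astype(str))


def simulate_genome(length: int, coding_fraction: float = 0.785,
                    at_coding: float = 0.881, at_intergenic: float = 0.938,
                    seed: int = 0, mean_gene_length: int = 800,
                    name: str = "synthetic_plastome",
                    ) -> tuple[SequenceRecord, FeatureTable]:
    """A genome of alternating coding/intergenic blocks with AT contrast.

    Gene and spacer lengths are drawn around ``mean_gene_length`` and the
    spacer size implied by ``coding_fraction``; bases are i.i.d. within
    each block at the block's target AT. At lengths >= 10 kb the realized
    per-kind AT is within ~2 percentage points of the targets.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1 kb")
    if not 0 < coding_fraction < 1:
        raise ValueError("coding_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    mean_spacer = mean_gene_length * (1 - coding_fraction) / coding_fraction
    features: list[Feature] = []
    chunks: list[str] = []
    pos = 0
    gene_i = 0
    while pos < length:
        for kind, mean_len, at in (("protein_coding", mean_gene_length,
                                    at_coding),
                                   ("intergenic", mean_spacer,
                                    at_intergenic)):
            if pos >= length:
                break
            n = int(min(max(50, rng.normal(mean_len, mean_len * 0.2)),
                        length - pos))
            chunks.append(_random_bases(n, at, rng))
            gene_i += 1
            features.append(Feature(
                seq_id=name, start=pos, end=pos + n,
                strand="+" if rng.random() < 0.5 else "-",
                kind=kind,
                name=(f"orf{gene_i}" if kind == "protein_coding"
                      else f"igs{gene_i}")))
            pos += n
    genome = SequenceRecord(name, "".join(chunks))
    return genome, FeatureTable(tuple(features))


def simulate_kmer_histogram(genome_size: int, coverage: float,
                            error_rate: float = 0.01, k: int = 21,
                            read_len: int = 150,
                            seed: int = 0) -> KmerHistogram:
    """A k-mer spectrum with an error peak and a genome peak.

    Each of ~``genome_size`` distinct genomic k-mers receives a Poisson
    multiplicity at the k-mer coverage implied by the read coverage
    (coverage * (read_len - k + 1) / read_len); sequencing errors add
    mostly-unique k-mers piled up at multiplicity 1. The genome peak sits
    near the k-mer coverage, so mass-over-peak recovers ``genome_size``.
    """
    if genome_size < k:
        raise ValueError("genome_size must be at least k")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    kmer_cov = coverage * (read_len - k + 1) / read_len
    genomic = rng.poisson(kmer_cov, size=genome_size)
    genomic = genomic[genomic > 0]
    # each base error corrupts up to k overlapping k-mers
    n_err = int(genome_size * coverage * error_rate * k / read_len * 10)
    bins = np.bincount(genomic)
    if n_err > 0:
        err = 1 + rng.poisson(0.05, size=n_err)
        err_bins = np.bincount(err)
        width = max(len(bins), len(err_bins))
        bins = np.pad(bins, (0, width - len(bins)))
        bins += np.pad(err_bins, (0, width - len(err_bins)))
    mult = np.nonzero(bins)[0]
    mult = mult[mult >= 1]
    return KmerHistogram(multiplicities=mult, counts=bins[mult], k=k)
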