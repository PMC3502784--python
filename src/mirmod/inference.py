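"""Modulation-network inference: triplet scoring, permutation significance,
Fisher pooling across shared targets, and network assembly.

For every candidate triplet (miR_a, miR_b, m) — where m is a known target
of at least one of the two miRNAs — the modulation statistic ΔMI is scored
against a permutation null obtained by shuffling the modulator's expression
across samples (the miRNA pair stays fixed, so the null preserves the pair's
marginal dependence while destroying any modulator-linked structure).  The
empirical p-value uses the add-one rule

    p = (1 + #{ΔMI_perm ≥ ΔMI_obs}) / (n_perm + 1)

which keeps p strictly positive: Fisher's method takes ln(p) and is
undefined at p = 0.  Triplet p-values for one unordered miRNA pair (pooled
over both orientations and all mediating targets) are combined as
X² = −2·Σ ln p_k against a chi-square with 2N degrees of freedom, and pairs
with combined p below the significance threshold become undirected edges of
the miRNA–miRNA network.

The default threshold is exp(−5) ≈ 6.74e−3, the literal reading of the
method's published cutoff; pass ``alpha`` explicitly for 1e−5 or any other
policy.  Permutation streams are derived per triplet by hashing the triplet
identifiers together with the master seed, so results do not depend on
candidate iteration order.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .information import (
    DEFAULT_BINS,
    DEFAULT_COND_BINS,
    DEFAULT_STRATA,
    ModulationScore,
    StratifiedMIWorker,
    discretize,
    mutual_information,
)
from .io import ExpressionMatrix, TargetNetwork

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = math.exp(-5.0)

__all__ = [
    "DEFAULT_ALPHA",
    "ModulationTriplet",
    "PairScore",
    "MiRNANetwork",
    "enumerate_candidates",
    "permutation_p",
    "fisher_combine",
    "infer_network",
    "write_network_outputs",
]


@dataclass
class ModulationTriplet:
    """One scored (miR_a, miR_b | modulator) candidate."""

    mir_a: str
    mir_b: str
    modulator: str
    score: ModulationScore
    p_value: float


@dataclass
class PairScore:
    """Fisher-combined evidence for one unordered miRNA pair."""

    mir_a: str
    mir_b: str
    x2: float
    dof: int
    combined_p: float
    n_targets: int
    mediating_targets: list[str] = field(default_factory=list)


@dataclass
class MiRNANetwork:
    """Undirected miRNA–miRNA network plus its full score tables.

    ``pairs`` holds one row per tested pair (not only surviving edges);
    ``triplets`` the per-triplet scores where applicable.  The graph itself
    contains only significant edges, stored once in canonical (sorted)
    orientation with their scores as edge attributes.
    """

    graph: nx.Graph
    pairs: pd.DataFrame
    triplets: Optional[pd.DataFrame] = None

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def connectivity(self) -> dict[str, int]:
        return {n: int(d) for n, d in self.graph.degree()}


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def enumerate_candidates(
    targets: TargetNetwork,
    mir: ExpressionMatrix,
    mrna: ExpressionMatrix,
    strict: bool = False,
) -> list[tuple[str, str, str]]:
    """All (miR_a, miR_b, modulator) candidates implied by the target table.

    For every resolvable target edge (a, m) the anchored miRNA a is paired
    with every other miRNA b in the expression matrix.  With ``strict=True``
    only pairs for which m is a shared target (m ∈ targets(a) ∩ targets(b))
    are kept.  Each unordered pair + modulator is returned once, in sorted
    order; unresolvable identifiers are dropped with logged counts.
    """
    resolvable = []
    dropped_mir = dropped_mrna = 0
    for a, m in targets.edges:
        if a not in mir:
            dropped_mir += 1
            continue
        if m not in mrna:
            dropped_mrna += 1
            continue
        resolvable.append((a, m))
    if dropped_mir or dropped_mrna:
        logger.info(
            "dropped %d edges with unknown miRNA and %d with unknown mRNA",
            dropped_mir,
            dropped_mrna,
        )
    if not resolvable:
        raise ValueError("no target edges resolvable against the expression matrices")
    edge_set = set(resolvable)
    out: set[tuple[str, str, str]] = set()
    for a, m in resolvable:
        for b in mir.feature_ids:
            if b == a:
                continue
            if strict and (b, m) not in edge_set:
                continue
            x, y = _canonical(a, b)
            out.add((x, y, m))
    return sorted(out)


def triplet_seed(mir_a: str, mir_b: str, modulator: str, master_seed: int) -> int:
    """Per-triplet RNG seed from a stable hash of ids and the master seed."""
    key = f"{mir_a}\t{mir_b}\t{modulator}\t{master_seed}".encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _permutation_p_worker(
    mi_marginal: float,
    worker: StratifiedMIWorker,
    labels: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """(conditional MI, ΔMI, p) for one triplet given precomputed state."""
    cmi_obs = worker.cmi(labels)
    delta_obs = abs(mi_marginal - cmi_obs)
    exceed = 0
    for _ in range(n_perm):
        cmi_perm = worker.cmi(rng.permutation(labels))
        if abs(mi_marginal - cmi_perm) >= delta_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return cmi_obs, delta_obs, p


def permutation_p(
    d,
    r,
    m,
    n_perm: int = 1000,
    seed: int = 0,
    B: int = DEFAULT_BINS,
    cond_B: int = DEFAULT_COND_BINS,
    S: int = DEFAULT_STRATA,
) -> tuple[ModulationScore, float]:
    """Permutation significance of the modulation statistic for one triplet.

    Only the modulator is shuffled; for a tie-free modulator this is
    implemented as shuffling its stratum labels, which is equivalent (the
    equal-frequency stratification commutes with sample permutation) and
    avoids re-sorting.  Reproducible under a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d = np.asarray(d, dtype=float)
    r = np.asarray(r, dtype=float)
    m = np.asarray(m, dtype=float)
    marginal = mutual_information(d, r, B)
    worker = StratifiedMIWorker(d, r, cond_B, S)
    labels = discretize(m, S)
    min_stratum = int(np.bincount(labels, minlength=S).min())
    if min_stratum < 2 * cond_B:
        raise ValueError(
            f"smallest modulator stratum has {min_stratum} samples; "
            f"at least 2B={2 * cond_B} required"
        )
    rng = np.random.default_rng(seed)
    cmi_obs, delta_obs, p = _permutation_p_worker(
        marginal.value, worker, labels, n_perm, rng
    )
    score = ModulationScore(
        mi_marginal=marginal,
        mi_conditional=cmi_obs,
        delta_mi=delta_obs,
        strata=S,
    )
    return score, p


def fisher_combine(p_values: Iterable[float]) -> tuple[float, int, float]:
    """Fisher's method: X² = −2·Σ ln p_k, referred to chi-square with 2N dof.

    Returns (x2, dof, combined_p).  Every p must lie in (0, 1]; the add-one
    permutation rule upstream guarantees this.
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise ValueError("fisher_combine requires at least one p-value")
    if np.any(ps <= 0.0) or np.any(ps > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = float(-2.0 * np.log(ps).sum())
    dof = 2 * ps.size
    combined_p = float(stats.chi2.sf(x2, dof))
    return x2, dof, combined_p


def infer_network(
    mir: ExpressionMatrix,
    mrna: ExpressionMatrix,
    targets: TargetNetwork,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = 1000,
    bins: int = DEFAULT_BINS,
    cond_bins: int = DEFAULT_COND_BINS,
    strata: int = DEFAULT_STRATA,
    seed: int = 0,
    strict: bool = False,
    bh: bool = False,
) -> MiRNANetwork:
    """Run the full modulation-network inference.

    Enumerates candidates, scores each triplet against its permutation null,
    pools triplet p-values per unordered miRNA pair with Fisher's method and
    keeps pairs with combined p < ``alpha`` as undirected edges.  With
    ``bh=True`` the threshold is applied to Benjamini–Hochberg-adjusted
    combined p-values instead.  Full triplet and pair tables are retained on
    the returned network for export.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if mir.sample_ids != mrna.sample_ids:
        raise ValueError(
            "miRNA and mRNA matrices must be sample-aligned (see align_samples)"
        )
    candidates = enumerate_candidates(targets, mir, mrna, strict=strict)
    logger.info("scoring %d candidate triplets (n_perm=%d)", len(candidates), n_perm)

    pair_state: dict[tuple[str, str], tuple[float, StratifiedMIWorker]] = {}
    label_cache: dict[str, np.ndarray] = {}
    rows = []
    for a, b, mgene in candidates:
        state = pair_state.get((a, b))
        if state is None:
            d = mir.row(a)
            r = mir.row(b)
            state = (
                mutual_information(d, r, bins).value,
                StratifiedMIWorker(d, r, cond_bins, strata),
            )
            pair_state[(a, b)] = state
        mi_marg, worker = state
        labels = label_cache.get(mgene)
        if labels is None:
            labels = discretize(mrna.row(mgene), strata)
            label_cache[mgene] = labels
        rng = np.random.default_rng(triplet_seed(a, b, mgene, seed))
        cmi, delta, p = _permutation_p_worker(mi_marg, worker, labels, n_perm, rng)
        rows.append((a, b, mgene, mi_marg, cmi, delta, p))

    triplets = pd.DataFrame(
        rows,
        columns=["mir_a", "mir_b", "modulator", "mi", "cmi", "delta_mi", "p_value"],
    )

    pair_rows = []
    for (a, b), grp in triplets.groupby(["mir_a", "mir_b"], sort=True):
        x2, dof, combined = fisher_combine(grp["p_value"])
        pair_rows.append(
            (a, b, x2, dof, combined, len(grp), ",".join(sorted(grp["modulator"])))
        )
    pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "mir_a", "mir_b", "x2", "dof", "combined_p", "n_targets",
            "mediating_targets",
        ],
    )
    if bh:
        from statsmodels.stats.multitest import multipletests

        pairs["combined_q"] = multipletests(pairs["combined_p"], method="fdr_bh")[1]
        significant = pairs["combined_q"] < alpha
    else:
        significant = pairs["combined_p"] < alpha
    pairs["significant"] = significant

    graph = nx.Graph()
    for row in pairs[significant].itertuples(index=False):
        graph.add_edge(
            row.mir_a,
            row.mir_b,
            x2=float(row.x2),
            dof=int(row.dof),
            combined_p=float(row.combined_p),
            n_targets=int(row.n_targets),
            mediating_targets=row.mediating_targets,
        )
    if graph.number_of_edges() == 0:
        logger.warning("no miRNA pair passed alpha=%g; network is empty", alpha)
    else:
        logger.info(
            "network: %d miRNAs, %d edges at alpha=%g",
            graph.number_of_nodes(),
            graph.number_of_edges(),
            alpha,
        )
    return MiRNANetwork(graph=graph, pairs=pairs, triplets=triplets)


def write_network_outputs(net: MiRNANetwork, outdir) -> None:
    """Write triplets.tsv, pairs.tsv, network.sif and network.graphml.

    The SIF file uses the interaction type ``mre`` and, like the GraphML
    export, is meant for Cytoscape.  Output is deterministic: rows are
    written in canonical sorted order with fixed float formatting.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if net.triplets is not None:
        net.triplets.sort_values(["mir_a", "mir_b", "modulator"]).to_csv(
            outdir / "triplets.tsv", sep="\t", index=False, float_format="%.10g"
        )
    net.pairs.sort_values(["mir_a", "mir_b"]).to_csv(
        outdir / "pairs.tsv", sep="\t", index=False, float_format="%.10g"
    )
    with open(outdir / "network.sif", "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\tmre\t{b}\n")
    ordered = nx.Graph()
    ordered.add_nodes_from(net.nodes)
    for a, b in sorted(net.edges):
        ordered.add_edge(a, b, **net.graph.edges[a, b])
    nx.write_graphml(ordered, outdir / "network.graphml")
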