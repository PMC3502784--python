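"""Synthetic paired miRNA/mRNA cohorts with planted modulation structure.

The generator emulates the shape of a matched tumor expression study — a
miRNA matrix and an mRNA matrix over the same samples, a miRNA→mRNA target
table, and per-sample class labels plus recurrence time/event — while
planting known ground truth for every downstream stage:

* **True modulation triplets** (miR_a, miR_b, m): the modulator transcript m
  is standard normal; samples with m above its median form a "high" stratum;
  within stratum s the miRNA pair is bivariate normal with correlation
  ``coupling_s``.  A stratum-dependent correlation is the minimal mechanism
  that makes MI(a,b|m) differ from MI(a,b).
* **A hub miRNA** participating in several true triplets (one common-factor
  miRNA with per-partner modulated loadings), so hub-degree recovery can be
  checked against ground truth.
* **Null triplets**: independent miRNA pairs attached to modulators they do
  not respond to; each null pair carries several candidate modulators, as
  real miRNA pairs share several candidate MREs.
* **Decoy target edges** on background miRNAs, giving the shared-target
  comparator network non-trivial, expression-free structure.
* **Class labels** (normal/primary/metastatic) with the planted signature
  (the true-triplet miRNAs) shifted down in tumors, and **exponential
  survival** with a configured hazard ratio between samples split on the
  signature's mean expression (low expression = high risk), censored
  administratively.

Everything is drawn from one seeded generator: a fixed seed fixes the full
output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, SampleMetadata, TargetNetwork

__all__ = [
    "PlantedTriplet",
    "SimulationConfig",
    "simulate_dataset",
    "planted_signature",
    "make_xor_fixture",
]


@dataclass(frozen=True)
class PlantedTriplet:
    """Ground-truth record for one planted (miR_a, miR_b, modulator) triplet."""

    mir_a: str
    mir_b: str
    modulator: str
    coupling_high: float
    coupling_low: float

    @property
    def is_null(self) -> bool:
        return self.coupling_high == self.coupling_low

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.mir_a, self.mir_b)))


@dataclass
class SimulationConfig:
    """Study conditions for :func:`simulate_dataset`.

    Defaults mirror a matched prostate-cohort shape: 139 samples with both
    data types, 370 miRNAs, class proportions 29 normal / 98 primary / 19
    metastatic (scaled to ``n_samples``), and a planted between-risk-group
    hazard ratio of 4.9.
    """

    n_samples: int = 139
    n_mirnas: int = 370
    n_mrnas: int = 1000
    n_true_triplets: int = 10
    n_null_triplets: int = 50
    coupling_high: float = 0.9
    coupling_low: float = 0.0
    null_coupling: float = 0.0
    noise_sd: float = 0.2
    hub_triplets: int = 6
    null_modulators_per_pair: int = 5
    n_decoy_edges: int = 100
    class_proportions: tuple[float, float, float] = (29.0, 98.0, 19.0)
    class_effect: float = 1.5
    risk_effect: float = 1.0
    hazard_ratio: float = 4.9
    baseline_hazard: float = 0.02
    censor_horizon: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ValueError(
                "n_samples must be >= 20 (modulator strata too small for "
                "conditional MI below that)"
            )
        for name in ("n_mirnas", "n_mrnas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_true_triplets", "n_null_triplets", "n_decoy_edges"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for c in (self.coupling_high, self.coupling_low, self.null_coupling):
            if not -1.0 <= c <= 1.0:
                raise ValueError("couplings must lie in [-1, 1]")
        if self.hub_triplets > self.n_true_triplets:
            raise ValueError("hub_triplets cannot exceed n_true_triplets")
        if self.null_modulators_per_pair < 1:
            raise ValueError("null_modulators_per_pair must be >= 1")
        if any(p < 0 for p in self.class_proportions) or sum(self.class_proportions) <= 0:
            raise ValueError("class_proportions must be nonnegative, not all zero")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard_ratio and baseline_hazard must be positive")


def _largest_remainder(weights, total: int) -> list[int]:
    """Apportion ``total`` into integer counts proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    quotas = weights / weights.sum() * total
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts.tolist()


def _modulated_partner(
    base: np.ndarray, modulator: np.ndarray, high: float, low: float, rng
) -> np.ndarray:
    """Draw a partner correlated ``high``/``low`` with ``base`` by m-stratum."""
    above = modulator > np.median(modulator)
    rho = np.where(above, high, low)
    return rho * base + np.sqrt(1.0 - rho**2) * rng.standard_normal(base.size)


def simulate_dataset(config: SimulationConfig):
    """Generate one synthetic cohort.

    Returns
    -------
    (mir, mrna, targets, metadata, planted) :
        miRNA and mRNA :class:`~mirmod.io.ExpressionMatrix` over the same
        samples, the miRNA→mRNA :class:`~mirmod.io.TargetNetwork` (planted
        anchor edges plus decoys), :class:`~mirmod.io.SampleMetadata` with
        class labels and survival columns, and the list of
        :class:`PlantedTriplet` ground-truth records (true then null).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples

    n_null_pairs = math.ceil(cfg.n_null_triplets / cfg.null_modulators_per_pair)
    n_hub = cfg.hub_triplets
    n_free = cfg.n_true_triplets - n_hub
    n_planted_mir = (1 + n_hub if n_hub else 0) + 2 * n_free + 2 * n_null_pairs
    if cfg.n_mirnas < n_planted_mir + (1 if cfg.n_decoy_edges else 0):
        raise ValueError(
            f"n_mirnas={cfg.n_mirnas} too small for {n_planted_mir} planted "
            "miRNAs plus background"
        )
    n_modulators = (1 if n_hub else 0) + n_free + cfg.n_null_triplets
    if cfg.n_mrnas < n_modulators + (1 if cfg.n_decoy_edges else 0):
        raise ValueError(
            f"n_mrnas={cfg.n_mrnas} too small for {n_modulators} modulators "
            "plus background"
        )

    mir_ids = [f"miR-{i + 1:03d}" for i in range(cfg.n_mirnas)]
    mrna_ids = [f"GENE-{j + 1:04d}" for j in range(cfg.n_mrnas)]
    sample_ids = [f"S{k + 1:03d}" for k in range(n)]

    mir_values = rng.standard_normal((cfg.n_mirnas, n))
    mrna_values = rng.standard_normal((cfg.n_mrnas, n))

    planted: list[PlantedTriplet] = []
    edges: set[tuple[str, str]] = set()
    next_mir = 0
    next_mrna = 0

    def take_mir() -> int:
        nonlocal next_mir
        next_mir += 1
        return next_mir - 1

    def take_mrna() -> int:
        nonlocal next_mrna
        next_mrna += 1
        return next_mrna - 1

    # --- hub star: one shared modulator (a single sponge transcript whose
    # MRE couples the hub to each partner) mediates all n_hub true triplets.
    # One modulator, not one per partner: each hub pair then has exactly one
    # mediating candidate, so the pair's Fisher combination is not diluted
    # by the hub's other (inert) targets.
    if n_hub:
        hub = take_mir()
        hub_expr = rng.standard_normal(n)
        mir_values[hub] = hub_expr
        mod = take_mrna()
        for _ in range(n_hub):
            partner = take_mir()
            mir_values[partner] = _modulated_partner(
                hub_expr, mrna_values[mod], cfg.coupling_high, cfg.coupling_low, rng
            )
            planted.append(
                PlantedTriplet(
                    mir_ids[hub],
                    mir_ids[partner],
                    mrna_ids[mod],
                    cfg.coupling_high,
                    cfg.coupling_low,
                )
            )
            edges.add((mir_ids[hub], mrna_ids[mod]))

    # --- remaining true triplets on disjoint fresh pairs ------------------
    for _ in range(n_free):
        a, b = take_mir(), take_mir()
        mod = take_mrna()
        mir_values[b] = _modulated_partner(
            mir_values[a], mrna_values[mod], cfg.coupling_high, cfg.coupling_low, rng
        )
        planted.append(
            PlantedTriplet(
                mir_ids[a], mir_ids[b], mrna_ids[mod],
                cfg.coupling_high, cfg.coupling_low,
            )
        )
        edges.add((mir_ids[a], mrna_ids[mod]))

    # --- null triplets: independent pairs, several inert modulators each --
    remaining_nulls = cfg.n_null_triplets
    for _ in range(n_null_pairs):
        a, b = take_mir(), take_mir()
        if cfg.null_coupling != 0.0:
            mir_values[b] = (
                cfg.null_coupling * mir_values[a]
                + math.sqrt(1.0 - cfg.null_coupling**2) * rng.standard_normal(n)
            )
        k = min(cfg.null_modulators_per_pair, remaining_nulls)
        remaining_nulls -= k
        for _ in range(k):
            mod = take_mrna()
            planted.append(
                PlantedTriplet(
                    mir_ids[a], mir_ids[b], mrna_ids[mod],
                    cfg.null_coupling, cfg.null_coupling,
                )
            )
            edges.add((mir_ids[a], mrna_ids[mod]))

    # --- decoy target edges on background miRNAs/mRNAs --------------------
    background_mirs = list(range(next_mir, cfg.n_mirnas))
    background_mrnas = list(range(next_mrna, cfg.n_mrnas))
    attempts = 0
    n_decoys_added = 0
    while n_decoys_added < cfg.n_decoy_edges:
        attempts += 1
        if attempts > 50 * cfg.n_decoy_edges + 100:
            raise ValueError("cannot place requested decoy edges without duplicates")
        edge = (
            mir_ids[rng.choice(background_mirs)],
            mrna_ids[rng.choice(background_mrnas)],
        )
        if edge not in edges:
            edges.add(edge)
            n_decoys_added += 1

    # --- class labels and the tumor shift on the planted signature --------
    counts = _largest_remainder(cfg.class_proportions, n)
    labels = np.array(
        ["normal"] * counts[0] + ["primary"] * counts[1] + ["metastatic"] * counts[2]
    )
    labels = labels[rng.permutation(n)]
    signature = sorted({t.mir_a for t in planted if not t.is_null}
                       | {t.mir_b for t in planted if not t.is_null})
    sig_rows = [mir_ids.index(s) for s in signature]
    tumor = labels != "normal"
    if sig_rows:
        mir_values[np.ix_(sig_rows, np.flatnonzero(tumor))] -= cfg.class_effect

    # --- risk strata: split on the signature's mean expression; the
    # high-risk (low-expression, aggressive) stratum is additionally shifted
    # down by risk_effect, modelling a subtype with globally silenced
    # tumor-suppressor miRNAs — and making the two risk groups a recoverable
    # cluster structure in signature space.
    if sig_rows:
        score = mir_values[sig_rows].mean(axis=0)
    else:
        score = mir_values.mean(axis=0)
    high_risk = score < np.median(score)  # low signature expression = aggressive
    if sig_rows and cfg.risk_effect:
        mir_values[np.ix_(sig_rows, np.flatnonzero(high_risk))] -= cfg.risk_effect

    # --- measurement noise on every feature -------------------------------
    if cfg.noise_sd > 0:
        mir_values += cfg.noise_sd * rng.standard_normal(mir_values.shape)
        mrna_values += cfg.noise_sd * rng.standard_normal(mrna_values.shape)

    # --- survival: exponential with planted HR between risk strata --------
    hazard = cfg.baseline_hazard * np.where(high_risk, cfg.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, cfg.censor_horizon, size=n)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    mir = ExpressionMatrix(mir_ids, sample_ids, mir_values)
    mrna = ExpressionMatrix(mrna_ids, sample_ids, mrna_values)
    targets = TargetNetwork(frozenset(edges), source_tag="synthetic")
    meta = SampleMetadata(sample_ids, list(labels), time, event)
    return mir, mrna, targets, meta, planted


def planted_signature(planted: list[PlantedTriplet]) -> list[str]:
    """The miRNAs participating in true (non-null) planted triplets, sorted."""
    return sorted(
        {t.mir_a for t in planted if not t.is_null}
        | {t.mir_b for t in planted if not t.is_null}
    )


def make_xor_fixture(n_per_cell: int):
    """Binary XOR triplet: zero marginal MI, conditional MI exactly ln 2.

    In the m=0 stratum ``b = a``; in the m=1 stratum ``b = 1 − a``, with
    all four (m, a) cells balanced at ``n_per_cell`` samples.  On the
    2-bin / 2-stratum estimator this gives MI(a,b)=0 and MI(a,b|m)=ln 2 by
    construction, hence ΔMI = ln 2 — the canonical case where conditioning
    reveals structure invisible marginally.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    m = np.repeat([0.0, 0.0, 1.0, 1.0], n_per_cell)
    a = np.repeat([0.0, 1.0, 0.0, 1.0], n_per_cell)
    b = np.where(m == 0, a, 1.0 - a)
    return a, b, m
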