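"""Synthetic fitness matrices with planted module structure.

The generator mirrors the generative picture behind the decomposition: a
sparse, heavy-tailed gene-weight matrix M (a few member genes per module
with large-magnitude signed weights, everything else exactly zero) times a
condition-activity matrix A, plus Gaussian measurement noise.  This is the
situation where a gene's fitness effect is strong and condition-specific —
e.g. disrupting an efflux gene is costly only when the toxin is present —
which drives per-module gene-weight distributions to the non-Gaussian,
outlier-dominated shape that ICA exploits.

All randomness flows from one ``numpy`` generator keyed by the seed, with a
fixed draw order (weights, then activities, then noise, then missing mask),
so outputs are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import FitnessMatrix, ModuleSet

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate",
    "truth_match",
    "recovery_report",
]


@dataclass
class SyntheticConfig:
    """Knobs for the planted-module generator.

    Defaults plant 8 disjoint-by-default modules of 5-15 genes into an
    800 x 64 matrix with weight magnitudes 3-6, 5% of member genes shared
    between two modules, and noise sd 0.25 — a regime where modules are
    recoverable but not trivial.
    """

    n_genes: int = 800
    n_samples: int = 64
    n_modules: int = 8
    module_size_range: tuple[int, int] = (5, 15)
    weight_magnitude_range: tuple[float, float] = (3.0, 6.0)
    shared_gene_fraction: float = 0.05
    activity_model: str = "condition_blocks"
    noise_sd: float = 0.25
    missing_rate: float = 0.0
    n_empty_modules: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules > self.n_samples:
            raise ValueError(
                f"n_modules={self.n_modules} exceeds n_samples="
                f"{self.n_samples}: ICA cannot recover more components "
                "than samples"
            )
        lo, hi = self.module_size_range
        if lo < 0 or hi < lo:
            raise ValueError("module_size_range must be 0 <= lo <= hi")
        for name in ("shared_gene_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.activity_model not in ("condition_blocks", "dense_gaussian"):
            raise ValueError(f"unknown activity_model {self.activity_model!r}")
        if self.n_empty_modules < 0 or self.n_empty_modules > self.n_modules:
            raise ValueError("n_empty_modules must be in [0, n_modules]")


@dataclass
class SyntheticTruth:
    """Ground truth for a generated matrix.

    ``member_sets`` is exactly the nonzero pattern of ``planted_M``; signs
    record each member's weight sign.
    """

    planted_M: np.ndarray  # genes x K
    planted_A: np.ndarray  # K x samples
    member_sets: dict[str, set[str]]
    member_signs: dict[str, dict[str, int]]
    noise_sd: float
    seed: int
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def as_module_set(self) -> ModuleSet:
        return ModuleSet(modules={m: set(g) for m, g in self.member_sets.items()})


def generate(config: SyntheticConfig) -> tuple[FitnessMatrix, SyntheticTruth]:
    """Generate ``F = planted_M @ planted_A + noise`` plus a missing mask.

    Non-members are exactly zero in ``planted_M``; member weights have
    magnitudes uniform in ``weight_magnitude_range`` with random signs.
    Under ``condition_blocks`` each module is active in a contiguous block
    of samples (blocks partition the sample axis, so planted activities of
    distinct modules are orthogonal) and zero elsewhere; under
    ``dense_gaussian`` activities are i.i.d. standard normal.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, S, K = config.n_genes, config.n_samples, config.n_modules
    gene_ids = [f"g{i:04d}" for i in range(G)]
    sample_ids = [f"s{j:03d}" for j in range(S)]
    module_ids = [f"planted_{k}" for k in range(K)]
    n_active = K - config.n_empty_modules

    # --- member sets (disjoint base assignment, then optional sharing) ---
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=K)
    sizes[n_active:] = 0  # trailing modules configured empty
    if sizes.sum() > G:
        raise ValueError("module sizes exceed the gene universe")
    pool = rng.permutation(G)
    member_idx: dict[str, list[int]] = {}
    cursor = 0
    for k, mod in enumerate(module_ids):
        member_idx[mod] = sorted(pool[cursor : cursor + sizes[k]].tolist())
        cursor += sizes[k]

    n_shared = int(round(config.shared_gene_fraction * sizes.sum()))
    if n_shared and n_active >= 2:
        all_members = np.concatenate(
            [member_idx[m] for m in module_ids if member_idx[m]]
        )
        chosen = rng.choice(all_members, size=n_shared, replace=False)
        for g in chosen:
            home = [m for m in module_ids if g in member_idx[m]]
            others = [
                m
                for m in module_ids[:n_active]
                if m not in home
            ]
            if others:
                target = others[rng.integers(len(others))]
                member_idx[target] = sorted(member_idx[target] + [int(g)])

    # --- weights ---
    w_lo, w_hi = config.weight_magnitude_range
    M = np.zeros((G, K))
    for k, mod in enumerate(module_ids):
        idx = member_idx[mod]
        if not idx:
            continue
        mags = rng.uniform(w_lo, w_hi, size=len(idx))
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        M[idx, k] = mags * signs

    # --- activities ---
    if config.activity_model == "condition_blocks":
        A = np.zeros((K, S))
        bounds = np.linspace(0, S, K + 1).astype(int)
        for k in range(K):
            a, b = bounds[k], bounds[k + 1]
            block = rng.normal(0.0, 1.0, size=b - a)
            block[np.abs(block) < 0.2] = 0.2  # keep the module active
            A[k, a:b] = block
    else:
        A = rng.normal(0.0, 1.0, size=(K, S))

    # --- noise, then mask ---
    F = M @ A
    if config.noise_sd > 0:
        F = F + rng.normal(0.0, config.noise_sd, size=(G, S))
    mask = np.zeros((G, S), dtype=bool)
    if config.missing_rate > 0:
        mask = rng.random((G, S)) < config.missing_rate

    member_sets = {
        m: {gene_ids[i] for i in idx} for m, idx in member_idx.items()
    }
    member_signs = {
        m: {gene_ids[i]: int(np.sign(M[i, k])) for i in member_idx[m]}
        for k, m in enumerate(module_ids)
    }
    fm = FitnessMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, values=F, missing_mask=mask
    )
    truth = SyntheticTruth(
        planted_M=M,
        planted_A=A,
        member_sets=member_sets,
        member_signs=member_signs,
        noise_sd=config.noise_sd,
        seed=config.seed,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
    )
    return fm, truth


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def truth_match(
    recovered: ModuleSet,
    truth: SyntheticTruth | ModuleSet,
    min_jaccard: float = 0.0,
) -> dict:
    """Greedy one-to-one matching of recovered to planted modules.

    Pairs are taken in order of descending Jaccard index of the gene sets
    (ties broken by module id for determinism); pairs below ``min_jaccard``
    are not matched.  Returns per-match Jaccard/precision/recall and the
    unmatched module ids on both sides.
    """
    planted = (
        truth.as_module_set() if isinstance(truth, SyntheticTruth) else truth
    )
    pairs = []
    for rid, rgenes in recovered:
        for pid, pgenes in planted:
            j = jaccard(rgenes, pgenes)
            if j >= min_jaccard and j > 0:
                pairs.append((j, rid, pid))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    matches = []
    used_r: set[str] = set()
    used_p: set[str] = set()
    for j, rid, pid in pairs:
        if rid in used_r or pid in used_p:
            continue
        used_r.add(rid)
        used_p.add(pid)
        rgenes, pgenes = recovered.modules[rid], planted.modules[pid]
        inter = len(rgenes & pgenes)
        matches.append(
            {
                "recovered": rid,
                "planted": pid,
                "jaccard": j,
                "precision": inter / len(rgenes) if rgenes else 1.0,
                "recall": inter / len(pgenes) if pgenes else 1.0,
            }
        )
    return {
        "matches": matches,
        "unmatched_recovered": [
            m for m in recovered.module_ids if m not in used_r
        ],
        "unmatched_planted": [
            m for m in planted.module_ids if m not in used_p
        ],
    }


def recovery_report(decomposition, modules, truth: SyntheticTruth) -> dict:
    """Score a decomposition + membership against the planted truth.

    For every planted module reports the membership Jaccard of its matched
    recovered module (0 if unmatched) and the absolute Pearson correlation
    between the matched activity row and the planted activity row.
    Matching is by gene-set Jaccard (see :func:`truth_match`).
    """
    match = truth_match(modules, truth)
    module_order = modules.module_ids
    per_planted: dict[str, dict] = {
        pid: {"jaccard": 0.0, "activity_rho": 0.0, "recovered": None}
        for pid in truth.member_sets
    }
    pid_index = {pid: i for i, pid in enumerate(truth.member_sets)}
    for m in match["matches"]:
        rid, pid = m["recovered"], m["planted"]
        i = module_order.index(rid)
        j = pid_index[pid]
        a = decomposition.A[i] - decomposition.A[i].mean()
        b = truth.planted_A[j] - truth.planted_A[j].mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        rho = float(a @ b / (na * nb)) if na > 0 and nb > 0 else 0.0
        per_planted[pid] = {
            "jaccard": m["jaccard"],
            "activity_rho": abs(rho),
            "recovered": rid,
        }
    scored = {
        p: v
        for p, v in per_planted.items()
        if truth.member_sets[p]  # empty planted modules are not scored
    }
    return {
        "per_planted": per_planted,
        "min_jaccard": min(v["jaccard"] for v in scored.values()),
        "min_activity_rho": min(v["activity_rho"] for v in scored.values()),
        "n_unmatched_planted": len(match["unmatched_planted"]),
        "n_unmatched_recovered": len(match["unmatched_recovered"]),
    }
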