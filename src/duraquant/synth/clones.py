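"""Synthetic CARLIN allele tables from multi-organ clone seeding.

Each barcoded founder (hematopoietic stem/progenitor clone) receives a
unique edited allele sequence and seeds either one organ (probability
1 - p_multiorgan) or a random subset of >= 2 organs. Per seeded organ the
clone expands to a UMI count drawn from a heavy-tailed distribution
(shifted geometric by default, minimum 1 UMI). An allele-0 row carries the
configured fraction of total UMIs as the unedited locus. Lowering
``p_multiorgan`` mimics later barcode-induction timepoints, after systemic
progenitor migration has declined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from duraquant.clonal import AlleleTable, MIN_TOTAL_UMI

_BASES = np.array(list("ACGT"))


@dataclass
class CloneSimConfig:
    n_clones: int = 2000
    organs: tuple[str, ...] = ("dura", "calvarial_bm", "leg_bm", "spleen")
    p_multiorgan: float = 0.5
    seeding_weights: tuple[float, ...] | None = None
    expansion_mean: float = 5.0  # mean UMIs per seeded organ (geometric, min 1)
    unedited_fraction: float = 0.3
    seed: int = 0
    mouse_id: str = "sim"
    induction: str = ""

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("need at least one clone")
        if len(self.organs) < 1:
            raise ValueError("need at least one organ")
        if len(set(self.organs)) != len(self.organs):
            raise ValueError("organ labels must be unique")
        if not 0.0 <= self.p_multiorgan <= 1.0:
            raise ValueError("p_multiorgan must be in [0, 1]")
        if self.p_multiorgan > 0 and len(self.organs) < 2:
            raise ValueError("multi-organ seeding requires >= 2 organs")
        if self.expansion_mean < 1:
            raise ValueError("expansion_mean must be >= 1")
        if not 0.0 <= self.unedited_fraction < 1.0:
            raise ValueError("unedited_fraction must be in [0, 1)")
        if self.seeding_weights is not None:
            w = np.asarray(self.seeding_weights, dtype=float)
            if len(w) != len(self.organs) or np.any(w < 0) or w.sum() == 0:
                raise ValueError("seeding_weights must be non-negative, one per organ")


def _unique_sequences(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    seqs: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        chunk = _BASES[rng.integers(0, 4, size=(n - len(out), length))]
        for row in chunk:
            s = "".join(row)
            if s not in seqs:
                seqs.add(s)
                out.append(s)
    return out


def true_multiorgan_sharing(
    counts: pd.DataFrame, founder_organs: dict[int, tuple[str, ...]]
) -> dict[str, float]:
    """UMI-weighted multi-organ sharing implied by the founder map.

    Computed over edited alleles passing the total-UMI >= 2 filter (the
    statistic is defined on filtered tables; only single-organ singleton
    clones are affected). Exact enumeration, independent of the analysis
    code path.
    """
    ids = counts.index.get_level_values("allele_id")
    edited = counts[(ids != 0) & (counts.sum(axis=1) >= MIN_TOTAL_UMI)]
    edited_ids = edited.index.get_level_values("allele_id")
    is_multi = np.array([len(founder_organs[int(a)]) >= 2 for a in edited_ids])
    out = {}
    for organ in counts.columns:
        col = edited[organ].to_numpy()
        total = int(col.sum())
        if total == 0:
            out[organ] = float("nan")
            continue
        out[organ] = 100.0 * int(col[is_multi].sum()) / total
    return out


def simulate_allele_tables(config: CloneSimConfig) -> tuple[AlleleTable, dict]:
    """Simulate one mouse's allele table plus the founder-map ground truth.

    Returns ``(table, truth)``; ``truth["founder_organs"]`` maps allele_id to
    the tuple of seeded organs and ``truth["true_sharing"]`` holds the exact
    UMI-weighted multi-organ sharing per organ implied by that map.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_seed, rng_expand, rng_seq = [np.random.default_rng(c) for c in ss.spawn(3)]
    organs = list(config.organs)
    n_organs = len(organs)
    weights = (
        np.asarray(config.seeding_weights, dtype=float)
        if config.seeding_weights is not None
        else np.ones(n_organs)
    )
    weights = weights / weights.sum()

    counts = np.zeros((config.n_clones, n_organs), dtype=int)
    founder_organs: dict[int, tuple[str, ...]] = {}
    multi = rng_seed.random(config.n_clones) < config.p_multiorgan
    p_geom = 1.0 / config.expansion_mean
    for i in range(config.n_clones):
        if multi[i]:
            size = int(rng_seed.integers(2, n_organs + 1))
            idx = rng_seed.choice(n_organs, size=size, replace=False, p=weights)
        else:
            idx = np.array([rng_seed.choice(n_organs, p=weights)])
        counts[i, idx] = rng_expand.geometric(p_geom, size=len(idx))
        founder_organs[i + 1] = tuple(organs[j] for j in sorted(idx))

    total_edited = counts.sum()
    f = config.unedited_fraction
    unedited_total = int(round(f / (1.0 - f) * total_edited))
    organ_tot = counts.sum(axis=0)
    probs = organ_tot / organ_tot.sum() if organ_tot.sum() > 0 else weights
    unedited = rng_expand.multinomial(unedited_total, probs)

    seqs = _unique_sequences(rng_seq, config.n_clones + 1)
    index = pd.MultiIndex.from_arrays(
        [np.arange(config.n_clones + 1), seqs], names=["allele_id", "allele_seq"]
    )
    frame = pd.DataFrame(
        np.vstack([unedited, counts]), index=index, columns=organs
    )
    table = AlleleTable(
        counts=frame, mouse_id=config.mouse_id, induction=config.induction
    )
    truth = {
        "founder_organs": founder_organs,
        "true_sharing": true_multiorgan_sharing(frame, founder_organs),
        "total_edited_umis": int(total_edited),
        "unedited_umis": int(unedited.sum()),
    }
    return table, truth
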