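"""Truth-based performance metrics for the meta-analysis on synthetic data.

The recovery study plants well-separated true meta-QTL clusters on single
chromosomes and measures how often AIC selects the true number of
components, how well the consensus positions are estimated, and whether the
reported 95% CIs cover the true positions at their nominal rate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .meta import select_model


@dataclass
class RecoveryConfig:
    """Conditions for the K-recovery / coverage study.

    True loci are separated by at least ``separation_factor`` times the
    typical (mean) QTL position s.d., and each receives at least
    ``qtls_per_mqtl_range[0]`` member QTLs.
    """

    n_replicates: int = 200
    n_mqtl_range: tuple[int, int] = (2, 4)
    qtls_per_mqtl_range: tuple[int, int] = (4, 8)
    sigma_range: tuple[float, float] = (1.5, 2.5)
    separation_factor: float = 5.0
    group_length: float = 150.0
    k_max: int = 10

    @property
    def min_separation(self) -> float:
        return self.separation_factor * float(np.mean(self.sigma_range))


def simulate_recovery_chromosome(
    rng: np.random.Generator, cfg: RecoveryConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One synthetic chromosome: (positions, sigmas, true labels, true positions)."""
    n_mqtl = int(rng.integers(cfg.n_mqtl_range[0], cfg.n_mqtl_range[1] + 1))
    margin = cfg.min_separation
    true_pos: list[float] = []
    while len(true_pos) < n_mqtl:
        candidate = rng.uniform(margin, cfg.group_length - margin)
        if all(abs(candidate - p) >= cfg.min_separation for p in true_pos):
            true_pos.append(candidate)
    true_pos = np.sort(np.array(true_pos))
    positions, sigmas, labels = [], [], []
    for j, mu in enumerate(true_pos):
        n_q = int(rng.integers(cfg.qtls_per_mqtl_range[0], cfg.qtls_per_mqtl_range[1] + 1))
        s = rng.uniform(cfg.sigma_range[0], cfg.sigma_range[1], size=n_q)
        positions.extend(rng.normal(mu, s))
        sigmas.extend(s)
        labels.extend([j] * n_q)
    return (
        np.array(positions),
        np.array(sigmas),
        np.array(labels),
        true_pos,
    )


def run_recovery_study(cfg: RecoveryConfig, seed: int) -> dict:
    """Replicate the recovery experiment and aggregate the truth metrics.

    Returns K-selection rate, 95% CI coverage of the true positions (each
    true locus matched to the component holding the plurality of its member
    QTLs), and position-error summaries.
    """
    rng = np.random.default_rng(seed)
    n_correct_k = 0
    covered = 0
    n_loci = 0
    abs_errors: list[float] = []
    ses: list[float] = []
    for _ in range(cfg.n_replicates):
        x, s, labels, true_pos = simulate_recovery_chromosome(rng, cfg)
        res = select_model(x, s, k_max=cfg.k_max)
        if res.k == len(true_pos):
            n_correct_k += 1
        assign = res.assignments()
        # consensus position and se per component, from hard-assigned members
        comp_pos = np.full(res.k, np.nan)
        comp_se = np.full(res.k, np.nan)
        for j in range(res.k):
            idx = assign == j
            if not idx.any():
                continue
            w = 1.0 / s[idx] ** 2
            comp_pos[j] = np.sum(w * x[idx]) / np.sum(w)
            comp_se[j] = np.sqrt(1.0 / np.sum(w))
        for j, mu in enumerate(true_pos):
            members = assign[labels == j]
            comp = Counter(members.tolist()).most_common(1)[0][0]
            if np.isnan(comp_pos[comp]):
                continue
            n_loci += 1
            err = abs(comp_pos[comp] - mu)
            abs_errors.append(err)
            ses.append(comp_se[comp])
            if err <= 1.96 * comp_se[comp]:
                covered += 1
    return {
        "n_replicates": cfg.n_replicates,
        "k_selection_rate": n_correct_k / cfg.n_replicates,
        "ci_coverage": covered / n_loci if n_loci else float("nan"),
        "n_true_loci": n_loci,
        "mean_abs_position_error": float(np.mean(abs_errors)),
        "mean_se": float(np.mean(ses)),
    }
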