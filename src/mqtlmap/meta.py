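"""Meta-analysis of projected QTLs: a variance-weighted Gaussian mixture.

Model
-----
On one linkage group, the n projected QTL peaks x_i are treated as noisy
observations of K underlying meta-QTL positions.  Each observation carries
its own known standard deviation sigma_i, derived from its 95% CI width
(sigma_i = width / 3.92).  The likelihood is

    L(mu, pi) = prod_i  sum_k  pi_k * N(x_i; mu_k, sigma_i^2),

with component means mu_k and mixing proportions pi_k free and the
per-observation variances fixed.  K is chosen by minimising

    AIC(K) = -2 ln L + 2 (2K - 1)

over K = 1..min(10, n) (K means + K-1 free proportions).  QTLs are then
hard-assigned to the component with maximal posterior responsibility, and
each component becomes a meta-QTL whose consensus position is the
inverse-variance weighted mean of its members, with standard error
se = sqrt(1 / sum(1/sigma_i^2)) and 95% CI position +/- 1.96 se.

The EM optimisation is multi-start and fully deterministic: for small n all
contiguous partitions of the sorted positions seed one run each (optimal
hard clusters in 1-D are contiguous), supplemented by quantile, largest-gap
and seeded jittered starts; everything is computed on the sorted positions,
so results are invariant to input order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import GeneRecord, GenomicInterval, Trait
from .projection import ProjectedQTL

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2 * math.pi)
Z_95 = 1.96  # 95% normal multiplier, consistent with the CI = 3.92*sigma convention
PROPORTION_FLOOR = 1e-6

#: Above this number of contiguous-partition starts, fall back to the
#: quantile/gap/jitter schedule only.
_MAX_PARTITION_STARTS = 512
_N_JITTER_STARTS = 5
_JITTER_SEED = 1203


def n_parameters(k: int) -> int:
    """Free parameters of a K-component fixed-variance mixture: K means, K-1 proportions."""
    return 2 * k - 1


class QTLMixture:
    """Variance-weighted 1-D Gaussian mixture model for QTL positions.

    Parameters
    ----------
    positions : array-like of cM positions (projected QTL peaks)
    sigmas : array-like of per-QTL standard deviations (cM), all > 0
    """

    def __init__(self, positions: Sequence[float], sigmas: Sequence[float]):
        x = np.asarray(positions, dtype=float)
        s = np.asarray(sigmas, dtype=float)
        if x.ndim != 1 or s.shape != x.shape:
            raise ValueError("positions and sigmas must be 1-D and equal length")
        if x.size == 0:
            raise ValueError("need at least one observation")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(s))):
            raise ValueError("non-finite positions or sigmas")
        if np.any(s <= 0):
            raise ValueError("all sigmas must be positive")
        self._order = np.argsort(x, kind="stable")
        self.x = x[self._order]
        self.s2 = s[self._order] ** 2
        self.nobs = x.size

    # ------------------------------------------------------------------ fits

    def fit(self, k: int, tol: float = 1e-10, max_iter: int = 1000) -> "QTLMixtureResults":
        """Fit a K-component mixture by multi-start EM (deterministic)."""
        n = self.nobs
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        if k == 1:
            # closed form: inverse-variance weighted mean
            w = 1.0 / self.s2
            mu = float(np.sum(w * self.x) / np.sum(w))
            means = np.array([mu])
            props = np.array([1.0])
            ll = float(np.sum(self._log_obs_density(means, props)))
            resp = np.ones((n, 1))
            return self._results(k, means, props, ll, resp, converged=True, n_iter=0)
        means0, props0 = self._starts(k)
        means, props, ll, n_iter = self._em(means0, props0, tol, max_iter)
        resp = self._responsibilities(means, props)
        return self._results(
            k, means, props, ll, resp, converged=n_iter < max_iter, n_iter=n_iter
        )

    def select(
        self, k_max: int = 10, tol: float = 1e-10, max_iter: int = 1000
    ) -> "QTLMixtureResults":
        """Fit K = 1..min(k_max, n) and return the AIC-minimal fit.

        Ties are broken toward the smaller K.  The chosen results object
        carries the full AIC profile in ``aic_profile``.
        """
        best: Optional[QTLMixtureResults] = None
        profile = []
        for k in range(1, min(k_max, self.nobs) + 1):
            res = self.fit(k, tol=tol, max_iter=max_iter)
            profile.append({"k": k, "loglik": res.loglik, "aic": res.aic})
            if best is None or res.aic < best.aic:
                best = res
        best.aic_profile = pd.DataFrame(profile)
        return best

    # ------------------------------------------------------------ internals

    def _log_comp_density(self, means: np.ndarray) -> np.ndarray:
        """(n, K) log N(x_i; mu_k, sigma_i^2)."""
        d = self.x[:, None] - means[None, :]
        return -0.5 * (_LOG_2PI + np.log(self.s2)[:, None] + d * d / self.s2[:, None])

    def _log_obs_density(self, means: np.ndarray, props: np.ndarray) -> np.ndarray:
        return logsumexp(self._log_comp_density(means) + np.log(props)[None, :], axis=1)

    def _responsibilities(self, means: np.ndarray, props: np.ndarray) -> np.ndarray:
        logp = self._log_comp_density(means) + np.log(props)[None, :]
        logp -= logsumexp(logp, axis=1, keepdims=True)
        return np.exp(logp)

    def _weighted_block_params(self, blocks: list[np.ndarray], k: int) -> tuple[np.ndarray, np.ndarray]:
        w = 1.0 / self.s2
        means = np.empty(k)
        props = np.empty(k)
        for j, idx in enumerate(blocks):
            means[j] = np.sum(w[idx] * self.x[idx]) / np.sum(w[idx])
            props[j] = len(idx) / self.nobs
        return means, props

    def _starts(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic multi-start schedule: (S, k) means and proportions."""
        n = self.nobs
        means_list: list[np.ndarray] = []
        props_list: list[np.ndarray] = []

        def add_blocks(cuts: tuple[int, ...]) -> None:
            bounds = (0,) + cuts + (n,)
            blocks = [np.arange(a, b) for a, b in zip(bounds, bounds[1:])]
            m, p = self._weighted_block_params(blocks, k)
            means_list.append(m)
            props_list.append(p)

        if math.comb(n - 1, k - 1) <= _MAX_PARTITION_STARTS:
            for cuts in combinations(range(1, n), k - 1):
                add_blocks(cuts)
        else:
            # quantile split
            qcuts = tuple(round(j * n / k) for j in range(1, k))
            if len(set((0,) + qcuts + (n,))) == k + 1:
                add_blocks(qcuts)
            # largest-gap split
            gaps = np.diff(self.x)
            if gaps.size >= k - 1:
                gcuts = tuple(sorted(np.argsort(gaps, kind="stable")[-(k - 1):] + 1))
                if len(set((0,) + gcuts + (n,))) == k + 1:
                    add_blocks(gcuts)
            # jittered quantile means (seeded; x already sorted, so the
            # schedule is invariant to input permutation)
            rng = np.random.default_rng(_JITTER_SEED + k)
            span = self.x[-1] - self.x[0]
            scale = span / (2 * k) if span > 0 else np.sqrt(np.median(self.s2))
            base = np.quantile(self.x, (np.arange(k) + 0.5) / k)
            for _ in range(_N_JITTER_STARTS):
                means_list.append(base + rng.normal(0, scale, size=k))
                props_list.append(np.full(k, 1.0 / k))
        return np.array(means_list), np.array(props_list)

    def _em_iterate(
        self,
        means: np.ndarray,
        props: np.ndarray,
        tol: float,
        max_iter: int,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
        """Batched EM sweeps over a (S, k) bank of starts."""
        x, s2 = self.x, self.s2
        n = self.nobs
        inv_s2 = 1.0 / s2
        means = means.copy()
        props = np.clip(props, PROPORTION_FLOOR, None)
        props = props / props.sum(axis=1, keepdims=True)
        loglik = np.full(means.shape[0], -np.inf)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            d = x[None, :, None] - means[:, None, :]  # (S, n, k)
            logphi = -0.5 * (
                _LOG_2PI + np.log(s2)[None, :, None] + d * d * inv_s2[None, :, None]
            )
            logp = logphi + np.log(props)[:, None, :]
            lse = logsumexp(logp, axis=2)  # (S, n)
            new_loglik = lse.sum(axis=1)
            resp = np.exp(logp - lse[:, :, None])  # (S, n, k)
            w = resp * inv_s2[None, :, None]
            denom = w.sum(axis=1)
            means = (w * x[None, :, None]).sum(axis=1) / np.maximum(denom, 1e-300)
            props = resp.sum(axis=1) / n
            props = np.clip(props, PROPORTION_FLOOR, None)
            props /= props.sum(axis=1, keepdims=True)
            delta = np.abs(new_loglik - loglik)
            loglik = new_loglik
            if np.all(delta < tol):
                break
        return means, props, loglik, n_iter

    #: above this n the start bank is pruned after a coarse pass; below it,
    #: every start runs to full convergence (keeps small-n fits exhaustive)
    _TWO_PHASE_MIN_N = 11
    _COARSE_ITER = 60
    _N_REFINE = 8

    def _em(
        self,
        means0: np.ndarray,
        props0: np.ndarray,
        tol: float,
        max_iter: int,
    ) -> tuple[np.ndarray, np.ndarray, float, int]:
        """Multi-start EM; returns the best converged solution."""
        means, props = means0, props0
        total_iter = 0
        if self.nobs >= self._TWO_PHASE_MIN_N and means.shape[0] > self._N_REFINE:
            means, props, loglik, it = self._em_iterate(
                means, props, tol, self._COARSE_ITER
            )
            top = np.argsort(loglik, kind="stable")[::-1][: self._N_REFINE]
            means, props = means[top], props[top]
            total_iter += it
        means, props, loglik, it = self._em_iterate(means, props, tol, max_iter)
        total_iter += it
        n_iter = total_iter
        best = int(np.argmax(loglik))
        m, p = means[best], props[best]
        # one final E-step at the returned parameters for a consistent loglik
        ll = float(np.sum(self._log_obs_density(m, p)))
        order = np.argsort(m, kind="stable")
        return m[order], p[order], ll, n_iter

    def _results(
        self,
        k: int,
        means: np.ndarray,
        props: np.ndarray,
        loglik: float,
        resp_sorted: np.ndarray,
        converged: bool,
        n_iter: int,
    ) -> "QTLMixtureResults":
        # map responsibilities back to the original input order
        resp = np.empty_like(resp_sorted)
        resp[self._order] = resp_sorted
        return QTLMixtureResults(
            model=self,
            k=k,
            means=means,
            proportions=props,
            loglik=loglik,
            responsibilities=resp,
            converged=converged,
            n_iter=n_iter,
        )


@dataclass
class QTLMixtureResults:
    """Fit results: component positions, proportions, likelihood and AIC."""

    model: QTLMixture
    k: int
    means: np.ndarray
    proportions: np.ndarray
    loglik: float
    responsibilities: np.ndarray  # (n, k), original input order
    converged: bool
    n_iter: int
    aic_profile: Optional[pd.DataFrame] = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * n_parameters(self.k)

    def assignments(self) -> np.ndarray:
        """Hard component labels by maximal responsibility (ties -> left)."""
        return np.argmax(self.responsibilities, axis=1)

    def plot_aic_profile(self, ax=None):
        from .plotting import plot_aic_profile

        return plot_aic_profile(self, ax=ax)

    def summary(self) -> str:
        lines = [
            "Variance-weighted Gaussian mixture (fixed per-QTL variances)",
            f"  n obs: {self.model.nobs:>5d}    K: {self.k}",
            f"  log-likelihood: {self.loglik:.4f}",
            f"  AIC: {self.aic:.4f}  (p = {n_parameters(self.k)})",
            f"  converged: {self.converged} ({self.n_iter} EM iterations)",
            "  component   mean (cM)   proportion",
        ]
        for j, (m, p) in enumerate(zip(self.means, self.proportions), 1):
            lines.append(f"  {j:>9d}   {m:>9.3f}   {p:>10.4f}")
        return "\n".join(lines)


# ------------------------------------------------------ functional wrappers


def fit_mixture(
    positions: Sequence[float], sigmas: Sequence[float], k: int
) -> QTLMixtureResults:
    return QTLMixture(positions, sigmas).fit(k)


def select_model(
    positions: Sequence[float], sigmas: Sequence[float], k_max: int = 10
) -> QTLMixtureResults:
    return QTLMixture(positions, sigmas).select(k_max=k_max)


# ------------------------------------------------------------------- MQTLs


@dataclass
class MQTL:
    """A consensus locus merging co-locating QTLs from several experiments."""

    name: str
    trait: Trait
    linkage_group: str
    position: float
    ci_start: float
    ci_end: float
    se: float
    members: list[ProjectedQTL]
    n_experiments: int
    pve_percent: float
    physical: Optional[GenomicInterval] = None
    genes: Optional[list[GeneRecord]] = None

    @property
    def ci_width(self) -> float:
        return self.ci_end - self.ci_start


def _trait_prefix(trait: Trait) -> str:
    return "m" + trait.value.capitalize()


def extract_mqtls(
    fit: QTLMixtureResults,
    members: Sequence[ProjectedQTL],
    trait: Trait,
    linkage_group: str,
) -> list[MQTL]:
    """Turn a mixture fit into named meta-QTLs.

    Members are hard-assigned by maximal responsibility; each non-empty
    component yields an MQTL at the inverse-variance weighted mean of its
    members with se = sqrt(1/sum(1/sigma_i^2)) and a 95% CI.  PVE is the
    arithmetic mean of member R-squared values, as a percent.  Names follow
    the m{Trait}{group}-{rank} convention, ranked by position.
    """
    members = list(members)
    if len(members) != fit.model.nobs:
        raise ValueError("member list does not match the fitted observations")
    labels = fit.assignments()
    mqtls: list[MQTL] = []
    for j in range(fit.k):
        idx = [i for i, lab in enumerate(labels) if lab == j]
        if not idx:
            logger.info(
                "component %d on group %s empty after hard assignment; dropped",
                j,
                linkage_group,
            )
            continue
        sub = [members[i] for i in idx]
        w = np.array([1.0 / m.sigma**2 for m in sub])
        x = np.array([m.peak_pos for m in sub])
        position = float(np.sum(w * x) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        r2 = [m.source.r_squared for m in sub if m.source.r_squared is not None]
        pve = float(np.mean(r2) * 100) if r2 else float("nan")
        mqtls.append(
            MQTL(
                name="",
                trait=trait,
                linkage_group=linkage_group,
                position=position,
                ci_start=position - Z_95 * se,
                ci_end=position + Z_95 * se,
                se=se,
                members=sub,
                n_experiments=len({m.experiment_id for m in sub}),
                pve_percent=pve,
            )
        )
    mqtls.sort(key=lambda m: m.position)
    prefix = _trait_prefix(trait)
    for rank, m in enumerate(mqtls, 1):
        m.name = f"{prefix}{linkage_group}-{rank}"
    return mqtls


def filter_mqtls(mqtls: Sequence[MQTL], min_experiments: int = 2) -> list[MQTL]:
    """Keep MQTLs supported by at least ``min_experiments`` distinct experiments."""
    return [m for m in mqtls if m.n_experiments >= min_experiments]


def analyze_group(
    members: Sequence[ProjectedQTL],
    trait: Trait,
    linkage_group: str,
    k_max: int = 10,
) -> tuple[list[MQTL], QTLMixtureResults]:
    """Select K by AIC on one linkage group and extract its MQTLs."""
    positions = [m.peak_pos for m in members]
    sigmas = [m.sigma for m in members]
    fit = select_model(positions, sigmas, k_max=k_max)
    return extract_mqtls(fit, members, trait, linkage_group), fit
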