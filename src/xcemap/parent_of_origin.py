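"""Parent-of-origin effect on X-inactivation choice in reciprocal F1 crosses.

Reciprocal F1 females (A x B versus B x A, dam listed first) are
genetically matched but inherit the stronger Xce allele from opposite
parents. If the parental origin of the stronger allele matters, specimens
that inherited it maternally should show more extreme skewing than their
reciprocal counterparts.

Specimens are grouped by the unordered pair of Xce alleles their parents
carry (aggregating genetic backgrounds to gain power) and oriented by the
parental origin of the stronger allele. The statistic delta is the
unweighted mean over groups of

    mean(p-hat | strong allele maternal) - mean(p-hat | strong allele paternal)

where p-hat is a specimen-level inactivation estimate on the
strong-allele-active-fraction scale. Significance comes from shuffling the
orientation labels within each group (10,000 shuffles by default).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_tables import StrainPanel, XCIMeasurement, XCE_SERIES_ORDER
from .xci_model import XCIPosterior, canonical_fraction

logger = logging.getLogger(__name__)

STRONG_MATERNAL = "strong-maternal"
STRONG_PATERNAL = "strong-paternal"


@dataclass
class ReciprocalGroup:
    """Specimens sharing an unordered, unequal Xce allele pair."""

    allele_pair: tuple[str, str]                  # sorted by series strength, weak first
    p_hat: dict[str, float]                       # mouse -> estimate, strong-allele scale
    orientation: dict[str, str]                   # mouse -> STRONG_MATERNAL / STRONG_PATERNAL

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        mice = sorted(self.p_hat)
        vals = np.array([self.p_hat[m] for m in mice])
        is_mat = np.array([self.orientation[m] == STRONG_MATERNAL for m in mice])
        return vals, is_mat


@dataclass
class PoeResult:
    delta: float
    per_group: dict[tuple[str, str], float]
    null_deltas: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    sided: str = "two"


def specimen_estimates(
    measurements: Sequence[XCIMeasurement],
    method: str = "simple_mean",
    posterior: XCIPosterior | None = None,
    focal_of_mouse: Mapping[str, str] | None = None,
    count_policy: str = "jeffreys",
) -> dict[str, float]:
    """Per-mouse X-inactivation estimates p-hat.

    ``focal_of_mouse`` fixes the scale per mouse (fraction attributable to
    that strain's X); default is the dam, i.e. the maternal fraction.
    ``simple_mean`` averages the mouse's canonical fractions across its
    gene-tissue measurements; ``posterior_mean`` takes the posterior
    expectation of the latent p_i from a fitted model (whose own focal
    orientation then applies).
    """
    by_mouse: dict[str, list[XCIMeasurement]] = {}
    for m in measurements:
        by_mouse.setdefault(m.mouse_id, []).append(m)

    out: dict[str, float] = {}
    if method == "simple_mean":
        for mouse, ms in by_mouse.items():
            focal = (focal_of_mouse or {}).get(mouse, ms[0].dam)
            out[mouse] = float(
                np.mean([canonical_fraction(m, focal, count_policy) for m in ms])
            )
    elif method == "posterior_mean":
        if posterior is None:
            raise ValueError("posterior_mean requires a fitted posterior")
        for mouse in by_mouse:
            out[mouse] = float(posterior.p_samples(mouse).mean())
    else:
        raise ValueError(f"unknown specimen estimator {method!r}")
    return out


def build_reciprocal_groups(
    measurements: Sequence[XCIMeasurement],
    panel: StrainPanel,
    p_hat: Mapping[str, float] | None = None,
    series: Sequence[str] = XCE_SERIES_ORDER,
    count_policy: str = "jeffreys",
) -> list[ReciprocalGroup]:
    """Group mice by unordered Xce allele pair, oriented by the stronger allele.

    Mice from crosses homozygous for the Xce allele pair (equal alleles) are
    excluded from the headline statistic, as are alleles outside the series
    order. The per-mouse estimate is placed on the strong-allele-active
    scale: when ``p_hat`` was computed on the maternal scale it is
    complemented for strong-paternal mice.
    """
    order = {a: k for k, a in enumerate(series)}
    by_mouse: dict[str, XCIMeasurement] = {}
    for m in measurements:
        by_mouse.setdefault(m.mouse_id, m)
    if p_hat is None:
        p_hat = specimen_estimates(measurements, count_policy=count_policy)

    groups: dict[tuple[str, str], ReciprocalGroup] = {}
    n_skipped = 0
    for mouse, m in by_mouse.items():
        a_dam = panel.entries.get(m.dam, "unknown")
        a_sire = panel.entries.get(m.sire, "unknown")
        if a_dam not in order or a_sire not in order or a_dam == a_sire:
            n_skipped += 1
            continue
        pair = tuple(sorted((a_dam, a_sire), key=order.get))
        strong_is_dam = order[a_dam] > order[a_sire]
        orientation = STRONG_MATERNAL if strong_is_dam else STRONG_PATERNAL
        # p_hat is on the maternal (dam-focal) scale; the strong-allele scale
        # complements it when the strong allele came from the sire
        val = p_hat[mouse] if strong_is_dam else 1.0 - p_hat[mouse]
        g = groups.setdefault(pair, ReciprocalGroup(pair, {}, {}))
        g.p_hat[mouse] = val
        g.orientation[mouse] = orientation
    if n_skipped:
        logger.info("excluded %d mice (equal or unplaced Xce alleles)", n_skipped)
    return [groups[k] for k in sorted(groups)]


def poe_statistic(groups: Sequence[ReciprocalGroup]) -> tuple[float, dict[tuple[str, str], float]]:
    """Overall delta and per-group deltas (strong-maternal minus strong-paternal).

    Groups missing one orientation are dropped with a log message; the
    overall delta is the unweighted mean of the per-group deltas.
    """
    per_group: dict[tuple[str, str], float] = {}
    for g in groups:
        vals, is_mat = g.arrays()
        if is_mat.all() or (~is_mat).all():
            logger.info("group %s lacks one orientation; dropped", g.allele_pair)
            continue
        per_group[g.allele_pair] = float(vals[is_mat].mean() - vals[~is_mat].mean())
    if not per_group:
        raise ValueError("no group has both reciprocal orientations")
    delta = float(np.mean(list(per_group.values())))
    return delta, per_group


def permutation_test(
    groups: Sequence[ReciprocalGroup],
    n_perm: int = 10_000,
    seed: int = 0,
    sided: str = "two",
    weighted: bool = False,
) -> PoeResult:
    """Permutation test of the parent-of-origin effect.

    Orientation labels are shuffled independently within each group,
    preserving the group's orientation counts. The p-value uses the add-one
    estimator p = (1 + #{|delta*| >= |delta|}) / (1 + n_perm) (signed
    comparison for ``sided="one"``), so it is never exactly zero.
    """
    if sided not in ("two", "one"):
        raise ValueError("sided must be 'two' or 'one'")
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-value resolution is coarse", n_perm)

    usable = []
    for g in groups:
        vals, is_mat = g.arrays()
        if is_mat.any() and (~is_mat).any():
            usable.append((vals, is_mat))
    if not usable:
        raise ValueError("no group has both reciprocal orientations")

    weights = (
        np.array([len(v) for v, _ in usable], dtype=float) if weighted
        else np.ones(len(usable))
    )
    weights = weights / weights.sum()

    def overall(deltas: np.ndarray) -> np.ndarray:
        return deltas @ weights

    obs_deltas = np.array([v[m].mean() - v[~m].mean() for v, m in usable])
    delta_obs = float(overall(obs_deltas))
    _, per_group = poe_statistic(groups)

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed])))
    null = np.empty((n_perm, len(usable)))
    for k, (vals, is_mat) in enumerate(usable):
        n, n_mat = len(vals), int(is_mat.sum())
        # vectorized within-group shuffles: rank the first n_mat slots of a
        # random permutation as the maternal set for each replicate
        u = rng.random((n_perm, n))
        idx = np.argsort(u, axis=1)
        mat_mask = np.zeros((n_perm, n), dtype=bool)
        np.put_along_axis(mat_mask, idx[:, :n_mat], True, axis=1)
        sum_all = vals.sum()
        sum_mat = mat_mask @ vals
        null[:, k] = sum_mat / n_mat - (sum_all - sum_mat) / (n - n_mat)
    null_overall = overall(null)

    if sided == "two":
        extreme = np.abs(null_overall) >= abs(delta_obs) - 1e-12
    else:
        extreme = null_overall >= delta_obs - 1e-12
    p = (1.0 + int(extreme.sum())) / (1.0 + n_perm)
    return PoeResult(
        delta=delta_obs,
        per_group=per_group,
        null_deltas=null_overall,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        sided=sided,
    )


def exhaustive_p_value(groups: Sequence[ReciprocalGroup], sided: str = "two") -> float:
    """Exact p-value by enumerating all within-group label assignments.

    Oracle for small groups; enumerates the product of all
    choose(n, n_maternal) orientation assignments per group.
    """
    usable = []
    for g in groups:
        vals, is_mat = g.arrays()
        if is_mat.any() and (~is_mat).any():
            usable.append((vals, int(is_mat.sum())))
    obs_deltas = []
    for g in groups:
        vals, is_mat = g.arrays()
        if is_mat.any() and (~is_mat).any():
            obs_deltas.append(vals[is_mat].mean() - vals[~is_mat].mean())
    delta_obs = float(np.mean(obs_deltas))

    group_deltas: list[list[float]] = []
    for vals, n_mat in usable:
        n = len(vals)
        deltas = []
        for combo in itertools.combinations(range(n), n_mat):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            deltas.append(vals[mask].mean() - vals[~mask].mean())
        group_deltas.append(deltas)

    count = 0
    total = 0
    for combo in itertools.product(*group_deltas):
        d = float(np.mean(combo))
        total += 1
        if sided == "two":
            if abs(d) >= abs(delta_obs) - 1e-12:
                count += 1
        else:
            if d >= delta_obs - 1e-12:
                count += 1
    return count / total
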