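"""Synthetic genotype and expression data with serialized ground truth.

Two generators emulate the pipeline's input families:

* ``simulate_genotypes`` plants a phenotype-consistent haplotype interval
  in an otherwise random strain distribution pattern landscape, with
  configurable per-call discordance and missingness — the setting of the
  SDP association scan;
* ``simulate_xci`` draws allele-specific expression measurements from the
  same beta hierarchy the inference model assumes: per-mouse latent
  proportions around a cross mean set by relative Xce allele strengths,
  gene-tissue bias/precision at the measurement layer, an optional
  parent-of-origin shift on the log-odds scale, and either pyrosequencing
  (rounded fractions) or RNA-seq (binomial read counts) readout.

Default allele strengths are calibration constants chosen so heterozygote
means land in the 0.25-0.75 band typical of skewed mouse crosses; they are
configuration, not measured biology. Every dataset carries a ``SimTruth``
sidecar with the exact generating parameters, and all randomness flows from
a single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .io_tables import GenotypeTable, StrainPanel, Variant, XCIMeasurement
from .xci_model import beta_shapes

#: default Xce allele strengths, ordered a < e < b < c < d
DEFAULT_STRENGTHS: dict[str, float] = {
    "a": 1.0,
    "e": 1.25,
    "b": 1.55,
    "c": 2.3,
    "d": 3.2,
}


@dataclass
class CrossDesign:
    """One F1 cross in a simulated phenotyping experiment."""

    dam: str
    sire: str
    dam_allele: str
    sire_allele: str
    n_mice: int


@dataclass
class SimTruth:
    """Ground truth serialized alongside every simulated dataset."""

    planted_interval: tuple[str, int, int] | None = None
    mu_of_cross: dict = field(default_factory=dict)       # "damxsire" -> true mu (maternal scale)
    p_of_mouse: dict = field(default_factory=dict)
    beta_of_gt: dict = field(default_factory=dict)        # "gene|tissue" -> bias
    tau_of_gt: dict = field(default_factory=dict)
    theta_of_cross: dict = field(default_factory=dict)
    lambda_of_cross: dict = field(default_factory=dict)
    poe_shift: float = 0.0
    seed: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def strength_to_mean(w_maternal: float, w_paternal: float, poe_shift: float = 0.0) -> float:
    """Expected fraction of cells with the maternal X active.

    The X carrying the stronger allele more often stays active:
    mu = w_m / (w_m + w_p), so equal strengths give 0.5. A parent-of-origin
    shift is added on the log-odds scale (applied by the caller only when
    the stronger allele is maternal).
    """
    if w_maternal <= 0 or w_paternal <= 0:
        raise ValueError("allele strengths must be positive")
    mu = w_maternal / (w_maternal + w_paternal)
    if poe_shift != 0.0:
        mu = float(expit(logit(mu) + poe_shift))
    return mu


def simulate_genotypes(
    n_group0: int,
    n_group1: int,
    n_variants: int,
    span: tuple[int, int] = (99_000_000, 101_000_000),
    planted_interval: tuple[int, int] = (99_943_259, 100_119_750),
    chrom: str = "X",
    discord_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    reference_strain: str = "C57BL/6J",
) -> tuple[GenotypeTable, StrainPanel, SimTruth]:
    """Simulate a strain panel genotype table with a planted consistent interval.

    group0 strains (reference allele carriers, Xce^b-like, including the
    reference strain itself) and group1 strains (Xce^a-like) get perfectly
    phenotype-consistent SDPs inside the planted interval; outside it each
    non-reference strain's allele is an independent fair coin, redrawn if it
    happens to reproduce the phenotype partition exactly (so at zero noise
    every consistent variant lies inside the planted interval and the scan
    recovers it with certainty). Variants are forced onto both planted
    boundaries. Discordance then flips individual calls — including the
    reference strain's, which repolarizes the whole row — and missingness
    blanks them, in that order.
    """
    lo, hi = span
    if not (lo <= planted_interval[0] <= planted_interval[1] <= hi):
        raise ValueError("planted interval must lie inside the simulated span")
    if not (0 <= discord_rate < 1 and 0 <= missing_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed])))

    group0 = [reference_strain] + [f"B6-like{i:02d}" for i in range(1, n_group0)]
    group1 = [f"AJ-like{i:02d}" for i in range(n_group1)]
    strains = group0 + group1
    panel = StrainPanel(
        {**{s: "b" for s in group0}, **{s: "a" for s in group1}},
        reference_strain,
    )

    if n_variants < 2:
        raise ValueError("need at least 2 variants to anchor the planted boundaries")
    pool = np.setdiff1d(np.arange(lo, hi + 1), np.array(planted_interval))
    sampled = rng.choice(pool, size=n_variants - 2, replace=False)
    positions = np.sort(np.concatenate([sampled, np.array(planted_interval)]))
    inside = (positions >= planted_interval[0]) & (positions <= planted_interval[1])

    n_strains = len(strains)
    ref_base = rng.choice(list("ACGT"), size=n_variants)
    alt_base = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in ref_base]
    )

    # SDP bits before noise: planted rows follow the phenotype partition
    # exactly; outside rows are independent coins (reference strain fixed 0),
    # redrawn if they hit the phenotype pattern
    phenotype = np.array([1 if s in group1 else 0 for s in strains])
    bits = rng.integers(0, 2, size=(n_variants, n_strains))
    bits[:, 0] = 0
    outside = ~inside
    while True:
        clash = outside & (bits == phenotype).all(axis=1)
        if not clash.any():
            break
        redraw = rng.integers(0, 2, size=(int(clash.sum()), n_strains))
        redraw[:, 0] = 0
        bits[clash] = redraw
    bits[inside] = phenotype

    flip = rng.random((n_variants, n_strains)) < discord_rate
    bits = np.where(flip, 1 - bits, bits)
    blank = rng.random((n_variants, n_strains)) < missing_rate

    calls = np.empty((n_variants, n_strains), dtype=object)
    for i in range(n_variants):
        for j in range(n_strains):
            if blank[i, j]:
                calls[i, j] = None
            else:
                calls[i, j] = alt_base[i] if bits[i, j] else ref_base[i]

    variants = [
        Variant(f"sv{i:05d}", chrom, int(p), "wgs" if i % 2 else "array")
        for i, p in enumerate(positions)
    ]
    truth = SimTruth(
        planted_interval=(chrom, int(planted_interval[0]), int(planted_interval[1])),
        seed=seed,
    )
    return GenotypeTable(variants, strains, calls), panel, truth


def simulate_xci(
    design: Sequence[CrossDesign],
    genes: Sequence[str] = ("Xg1", "Xg2", "Xg3", "Xg4", "Xg5"),
    tissues: Sequence[str] = ("brain", "kidney", "liver"),
    strengths: Mapping[str, float] | None = None,
    theta_c: float | Mapping[str, float] = 60.0,
    beta_j: Mapping[tuple[str, str], float] | None = None,
    tau_j: float | Mapping[tuple[str, str], float] = 80.0,
    lambda_c: float | Mapping[str, float] = 1.0,
    poe_shift: float = 0.0,
    assay: str = "pyro",
    read_depth: int = 200,
    seed: int = 0,
) -> tuple[list[XCIMeasurement], SimTruth]:
    """Draw allele-specific expression data from the beta hierarchy.

    Per mouse i of cross c: p_i ~ Beta(mean mu_c, precision theta_c) with
    mu_c = strength_to_mean(dam, sire) on the maternal scale, plus
    ``poe_shift`` log-odds when the stronger allele is maternal. Per
    gene-tissue j: y_ij ~ Beta(mean expit(logit(p_i) + beta_j), precision
    tau_j * lambda_c). Pyro mode rounds fractions to 3 decimals
    (instrument resolution); rnaseq mode draws maternal read counts
    Binomial(read_depth, measurement mean).
    """
    if not design:
        raise ValueError("empty cross design")
    if assay not in ("pyro", "rnaseq"):
        raise ValueError(f"unknown assay mode {assay!r}")
    strengths = dict(DEFAULT_STRENGTHS if strengths is None else strengths)
    if any(w <= 0 for w in strengths.values()):
        raise ValueError("allele strengths must be positive")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed])))

    order = {a: k for k, a in enumerate(strengths)}
    gt_pairs = [(g, t) for g in genes for t in tissues]
    betas = {gt: 0.0 for gt in gt_pairs}
    if beta_j:
        betas.update({tuple(k): v for k, v in beta_j.items()})
    taus = {
        gt: (tau_j[gt] if isinstance(tau_j, Mapping) else float(tau_j))
        for gt in gt_pairs
    }
    if any(v <= 0 for v in taus.values()):
        raise ValueError("gene-tissue precisions must be positive")

    truth = SimTruth(poe_shift=poe_shift, seed=seed)
    truth.beta_of_gt = {f"{g}|{t}": betas[(g, t)] for g, t in gt_pairs}
    truth.tau_of_gt = {f"{g}|{t}": taus[(g, t)] for g, t in gt_pairs}

    measurements: list[XCIMeasurement] = []
    counter = 0
    for cd in design:
        key = f"{cd.dam}x{cd.sire}"
        w_m = strengths[cd.dam_allele]
        w_p = strengths[cd.sire_allele]
        strong_is_maternal = w_m > w_p
        shift = poe_shift if strong_is_maternal else 0.0
        mu = strength_to_mean(w_m, w_p, shift)
        th = theta_c[key] if isinstance(theta_c, Mapping) else float(theta_c)
        lam = lambda_c[key] if isinstance(lambda_c, Mapping) else float(lambda_c)
        if th <= 0 or lam <= 0:
            raise ValueError("theta_c and lambda_c must be positive")
        truth.mu_of_cross[key] = mu
        truth.theta_of_cross[key] = th
        truth.lambda_of_cross[key] = lam

        a, b = beta_shapes(mu, th)
        p = rng.beta(a, b, size=cd.n_mice)
        p = np.clip(p, 1e-6, 1 - 1e-6)
        for i in range(cd.n_mice):
            counter += 1
            mouse = f"m{counter:04d}"
            truth.p_of_mouse[mouse] = float(p[i])
            for g, t in gt_pairs:
                m_mean = float(expit(logit(p[i]) + betas[(g, t)]))
                am, bm = beta_shapes(m_mean, taus[(g, t)] * lam)
                y = float(rng.beta(am, bm))
                if assay == "pyro":
                    frac = round(min(max(y, 0.0), 1.0), 3)
                    measurements.append(
                        XCIMeasurement(
                            mouse_id=mouse, dam=cd.dam, sire=cd.sire,
                            tissue=t, gene=g, assay="pyro",
                            maternal_fraction=frac,
                        )
                    )
                else:
                    reads_m = int(rng.binomial(read_depth, y))
                    measurements.append(
                        XCIMeasurement(
                            mouse_id=mouse, dam=cd.dam, sire=cd.sire,
                            tissue=t, gene=g, assay="rnaseq",
                            maternal_reads=reads_m,
                            paternal_reads=read_depth - reads_m,
                        )
                    )
    return measurements, truth


def reciprocal_design(
    strain_a: str, allele_a: str, strain_b: str, allele_b: str, n_mice: int
) -> list[CrossDesign]:
    """Convenience: the pair of reciprocal crosses A x B and B x A."""
    return [
        CrossDesign(strain_a, strain_b, allele_a, allele_b, n_mice),
        CrossDesign(strain_b, strain_a, allele_b, allele_a, n_mice),
    ]
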