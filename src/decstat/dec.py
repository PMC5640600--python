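"""The disease-expression correlation (DEC) statistic.

DEC asks whether the regional association pattern of a disease and the
cis-eQTL pattern of a nearby gene look like the fingerprint of a shared
causal variant, and in which direction the risk allele moves expression.
Writing x_s = log10(1/p) of SNP s in the disease scan and y_s the same in
the eQTL scan:

* sigma = Spearman correlation of the unsigned (x, y) pairs — how similar
  the two association patterns are;
* Pen = 1 / (1 + exp(-k1 * (sigma - k2))) — a logistic penalty that
  crushes the statistic toward zero unless the patterns are strongly
  positively correlated (defaults k1 = 30, k2 = 0.3);
* SC = Spearman correlation of the signed points
  (sign(beta_dis) * x, sign(beta_eqtl) * y), each SNP contributing the
  allele-1-referenced point AND its joint negation (the allele-2-referenced
  point), which makes SC invariant to reference-allele choices;
* DEC = Pen * SC, in (-1, 1); its sign says whether the expression-raising
  allele raises (+) or lowers (-) disease risk.

Only "informative" SNPs — log10(1/p) >= 1.2 in at least one scan by
default — enter the computation; a sea of null SNPs carries no pattern
information and would dilute both correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from .association import PairedRegionScan

__all__ = [
    "PenaltyParams",
    "DECConfig",
    "SignedPointSet",
    "DECResult",
    "InformativeCountError",
    "filter_informative",
    "penalty",
    "signed_points",
    "spearman",
    "compute_dec",
]

logger = logging.getLogger(__name__)


class InformativeCountError(ValueError):
    """Raised when too few SNPs pass the informative filter."""

    def __init__(self, n_found: int, n_required: int):
        self.n_found = n_found
        self.n_required = n_required
        super().__init__(
            f"only {n_found} informative SNP(s) found; at least "
            f"{n_required} required for a meaningful correlation"
        )


@dataclass(frozen=True)
class PenaltyParams:
    """Constants of the logistic penalty: steepness k1, midpoint k2."""

    k1: float = 30.0
    k2: float = 0.3

    def __post_init__(self) -> None:
        if self.k1 <= 0:
            raise ValueError(f"k1 must be positive, got {self.k1}")


@dataclass(frozen=True)
class DECConfig:
    """Tunables of the DEC computation.

    ``informative_threshold`` is the log10(1/p) cutoff a SNP must reach in
    at least one scan (inclusive comparison); ``sigma_scope`` selects
    whether the unsigned pattern correlation sigma is computed on the
    informative subset (default) or on every harmonized SNP.
    """

    penalty: PenaltyParams = field(default_factory=PenaltyParams)
    informative_threshold: float = 1.2
    min_informative: int = 3
    sigma_scope: Literal["informative", "all"] = "informative"

    def __post_init__(self) -> None:
        if self.informative_threshold < 0:
            raise ValueError("informative_threshold must be >= 0")
        if self.min_informative < 2:
            raise ValueError("min_informative must be >= 2")
        if self.sigma_scope not in ("informative", "all"):
            raise ValueError(f"unknown sigma_scope {self.sigma_scope!r}")


@dataclass(frozen=True)
class SignedPointSet:
    """The duplicated signed scatter behind SC (two points per SNP).

    ``u`` carries sign(beta_disease) * log10(1/p_disease), ``v`` the eQTL
    analogue; entries 2k and 2k+1 are SNP k referenced to allele 1 and
    allele 2 respectively, so the set is symmetric under joint negation.
    """

    snp_ids: Sequence[str]
    ref_alleles: Sequence[str]
    u: np.ndarray
    v: np.ndarray

    def __len__(self) -> int:
        return len(self.u)


@dataclass(frozen=True)
class DECResult:
    """sigma, Pen, SC, DEC = Pen * SC and the informative-SNP count."""

    sigma: float
    penalty: float
    signed_correlation: float
    dec: float
    n_informative: int

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "penalty": self.penalty,
            "sc": self.signed_correlation,
            "dec": self.dec,
            "n_informative": self.n_informative,
        }


def penalty(sigma: float, params: PenaltyParams = PenaltyParams()) -> float:
    """Logistic penalty Pen = 1 / (1 + exp(-k1 * (sigma - k2))).

    Strictly increasing in sigma and bounded in (0, 1); equals 1/2 at the
    midpoint sigma = k2.
    """
    if not -1.0 <= sigma <= 1.0:
        raise ValueError(f"sigma must lie in [-1, 1], got {sigma}")
    return float(1.0 / (1.0 + np.exp(-params.k1 * (sigma - params.k2))))


def filter_informative(scan: PairedRegionScan, config: DECConfig) -> PairedRegionScan:
    """Keep SNPs reaching the threshold in the disease or eQTL scan (or both).

    Order is preserved. Raises :class:`InformativeCountError` when fewer
    than ``config.min_informative`` SNPs survive.
    """
    thr = config.informative_threshold
    keep = [
        i
        for i, (rd, re_) in enumerate(zip(scan.records_disease, scan.records_eqtl))
        if rd.log1p >= thr or re_.log1p >= thr
    ]
    if len(keep) < config.min_informative:
        raise InformativeCountError(len(keep), config.min_informative)
    return replace(
        scan,
        records_disease=tuple(scan.records_disease[i] for i in keep),
        records_eqtl=tuple(scan.records_eqtl[i] for i in keep),
    )


def _signs(betas: np.ndarray, track: str) -> np.ndarray:
    s = np.where(betas >= 0.0, 1.0, -1.0)
    n_zero = int((betas == 0.0).sum())
    if n_zero:
        logger.warning(
            "%s track: %d zero effect estimate(s); sign taken as +", track, n_zero
        )
    return s


def signed_points(scan: PairedRegionScan) -> SignedPointSet:
    """Build the duplicated signed point set of an (informative) paired scan.

    Per SNP: (s_d * x, s_e * y) referenced to allele 1, plus its joint
    negation referenced to allele 2, where s = sign(beta) and x, y are the
    log10(1/p) values. Flipping any input SNP's reference allele leaves the
    resulting set unchanged.
    """
    x = np.array([r.log1p for r in scan.records_disease])
    y = np.array([r.log1p for r in scan.records_eqtl])
    s_d = _signs(np.array([r.beta for r in scan.records_disease]), "disease")
    s_e = _signs(np.array([r.beta for r in scan.records_eqtl]), "eQTL")
    u1, v1 = s_d * x, s_e * y
    u = np.empty(2 * len(x))
    v = np.empty(2 * len(x))
    u[0::2], u[1::2] = u1, -u1
    v[0::2], v[1::2] = v1, -v1
    ids: list[str] = []
    refs: list[str] = []
    for rd in scan.records_disease:
        ids.extend([rd.snp_id, rd.snp_id])
        refs.extend([rd.allele1, rd.allele2])
    return SignedPointSet(snp_ids=tuple(ids), ref_alleles=tuple(refs), u=u, v=v)


def spearman(u: np.ndarray, v: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of midranks.

    Ties receive average ranks, which the duplicated point set guarantees
    (every |value| appears twice). Raises on constant input, where the
    correlation is undefined.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be 1-D of equal length")
    if len(u) < 2:
        raise ValueError("need at least 2 points")
    ru = rankdata(u)
    rv = rankdata(v)
    ru_c = ru - ru.mean()
    rv_c = rv - rv.mean()
    denom = np.sqrt((ru_c @ ru_c) * (rv_c @ rv_c))
    if denom == 0.0:
        raise ValueError("Spearman correlation undefined: constant input vector")
    return float(np.clip((ru_c @ rv_c) / denom, -1.0, 1.0))


def compute_dec(scan: PairedRegionScan, config: DECConfig = DECConfig()) -> DECResult:
    """Full DEC computation on a harmonized paired scan.

    Applies the informative filter, computes sigma on the unsigned patterns,
    the logistic penalty, SC on the duplicated signed point set, and
    DEC = Pen * SC.
    """
    informative = filter_informative(scan, config)
    sigma_scan = scan if config.sigma_scope == "all" else informative
    x = np.array([r.log1p for r in sigma_scan.records_disease])
    y = np.array([r.log1p for r in sigma_scan.records_eqtl])
    sigma = spearman(x, y)
    pen = penalty(sigma, config.penalty)
    points = signed_points(informative)
    sc = spearman(points.u, points.v)
    return DECResult(
        sigma=sigma,
        penalty=pen,
        signed_correlation=sc,
        dec=pen * sc,
        n_informative=len(informative),
    )
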