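"""Per-SNP association scans and allele harmonization.

Two single-SNP scans over a region:

* :func:`eqtl_scan` — ordinary least squares of a continuous expression
  trait on allele-1 dosage (intercept + slope), two-sided t test on the
  slope with n - 2 degrees of freedom;
* :func:`disease_scan` — logistic regression of case status on dosage,
  fitted per SNP by Newton scoring (iteratively reweighted least squares),
  two-sided Wald test on the log-odds slope.

Both scans report the effect of allele 1, so flipping which allele is
called "allele 1" negates beta and leaves the p-value unchanged.
:func:`harmonize` aligns two scans onto a common SNP set with a common
allele-1 orientation, which is what the DEC statistic consumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import special, stats

from .simulate import RegionDataset

__all__ = [
    "AssociationRecord",
    "PairedRegionScan",
    "eqtl_scan",
    "disease_scan",
    "harmonize",
]

logger = logging.getLogger(__name__)

MAX_IRLS_ITER = 100
IRLS_GRAD_TOL = 1e-8
_P_FLOOR = 5e-324  # smallest subnormal; p-values are floored here, never 0


@dataclass(frozen=True, slots=True)
class AssociationRecord:
    """Summary statistics of one SNP in one scan.

    ``beta`` is the signed per-allele-1-dosage effect (expression units per
    allele for the eQTL scan, log-odds per allele for the disease scan);
    ``p`` is the two-sided p-value in (0, 1].
    """

    snp_id: str
    position: int
    allele1: str
    allele2: str
    beta: float
    se: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.snp_id}: p must lie in (0, 1], got {self.p}")

    @property
    def log1p(self) -> float:
        """log10(1/p), the association-strength coordinate of the patterns."""
        return -math.log10(self.p)

    def flipped(self) -> "AssociationRecord":
        """The same association referenced to the other allele."""
        return replace(
            self, allele1=self.allele2, allele2=self.allele1, beta=-self.beta
        )


@dataclass(frozen=True)
class PairedRegionScan:
    """Disease and eQTL tracks over the same SNPs in the same orientation.

    Produced by :func:`harmonize`; both record lists share snp_id order and
    per-SNP allele labels. ``n_flipped`` counts SNPs whose eQTL record was
    re-referenced to match the disease track; ``dropped_disease`` /
    ``dropped_eqtl`` list snp_ids excluded from each input (absent from the
    intersection or carrying irreconcilable allele pairs).
    """

    records_disease: Tuple[AssociationRecord, ...]
    records_eqtl: Tuple[AssociationRecord, ...]
    n_flipped: int = 0
    dropped_disease: Tuple[str, ...] = ()
    dropped_eqtl: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids_d = [r.snp_id for r in self.records_disease]
        ids_e = [r.snp_id for r in self.records_eqtl]
        if ids_d != ids_e:
            raise ValueError("paired tracks must share snp_id order")
        if len(set(ids_d)) != len(ids_d):
            raise ValueError("duplicate snp_id in paired scan")
        for rd, re_ in zip(self.records_disease, self.records_eqtl):
            if (rd.allele1, rd.allele2) != (re_.allele1, re_.allele2):
                raise ValueError(f"{rd.snp_id}: allele pairs differ between tracks")

    def __len__(self) -> int:
        return len(self.records_disease)


def _polymorphic_mask(dosages: np.ndarray) -> np.ndarray:
    return dosages.min(axis=0) != dosages.max(axis=0)


def _records_from_arrays(
    data: RegionDataset, idx: np.ndarray, beta, se, p
) -> List[AssociationRecord]:
    return [
        AssociationRecord(
            snp_id=data.snp_ids[j],
            position=int(data.positions[j]),
            allele1=str(data.allele1[j]),
            allele2=str(data.allele2[j]),
            beta=float(beta[k]),
            se=float(se[k]),
            p=float(p[k]),
        )
        for k, j in enumerate(idx)
    ]


def linear_scan_arrays(
    dosages: np.ndarray, y: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized simple OLS of ``y`` on each dosage column.

    Returns (kept column indices, beta, se, p); monomorphic columns are
    excluded from the kept set. Shared by the eQTL scan and the in-silico
    eQTL null, where thousands of scans run on the same genotype matrix.
    """
    n = dosages.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals for the t test")
    mask = _polymorphic_mask(dosages)
    idx = np.nonzero(mask)[0]
    g = dosages[:, idx].astype(float)
    yc = y - y.mean()
    gc = g - g.mean(axis=0)
    sxx = (gc * gc).sum(axis=0)
    sxy = gc.T @ yc
    beta = sxy / sxx
    syy = float(yc @ yc)
    rss = np.maximum(syy - beta * sxy, 0.0)
    dof = n - 2
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), dof), _P_FLOOR)
    return idx, beta, se, p


def eqtl_scan(data: RegionDataset) -> List[AssociationRecord]:
    """Linear-regression eQTL scan: expression ~ intercept + dosage, per SNP.

    Monomorphic SNPs are dropped with a logged warning (a slope on a
    constant regressor is undefined), never emitted as NaN records.
    """
    if data.expression is None:
        raise ValueError("dataset has no expression phenotype")
    idx, beta, se, p = linear_scan_arrays(data.dosages, np.asarray(data.expression, float))
    n_dropped = data.n_snps - idx.size
    if n_dropped:
        dropped = sorted(set(range(data.n_snps)) - set(idx.tolist()))
        logger.warning(
            "eqtl_scan: dropped %d monomorphic SNP(s): %s",
            n_dropped,
            ", ".join(data.snp_ids[j] for j in dropped),
        )
    return _records_from_arrays(data, idx, beta, se, p)


def logistic_scan_arrays(
    dosages: np.ndarray, y: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP logistic regression of ``y`` on each dosage column.

    Newton scoring on the 2-parameter model (intercept, slope) for all
    polymorphic columns at once, iterated to gradient sup-norm <=
    ``IRLS_GRAD_TOL`` or ``MAX_IRLS_ITER`` iterations. Returns (kept column
    indices, beta, se, p, converged mask). Non-converged columns (perfect or
    quasi-separation) keep the estimates at the iteration cap — the most
    significant finite values obtainable there — and are flagged False.
    """
    n = dosages.shape[0]
    y = np.asarray(y, float)
    if y.min() == y.max():
        raise ValueError("disease phenotype has a single class; scan undefined")
    mask = _polymorphic_mask(dosages)
    idx = np.nonzero(mask)[0]
    g = dosages[:, idx].astype(float)
    m = idx.size

    a = np.full(m, float(special.logit(np.clip(y.mean(), 1e-12, 1 - 1e-12))))
    b = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    h11_last = np.ones(m)
    det_last = np.ones(m)

    for _ in range(MAX_IRLS_ITER):
        eta = a[None, :] + g * b[None, :]
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        resid = y[:, None] - mu
        u1 = resid.sum(axis=0)
        u2 = (g * resid).sum(axis=0)
        h11 = w.sum(axis=0)
        h12 = (w * g).sum(axis=0)
        h22 = (w * g * g).sum(axis=0)
        det = h11 * h22 - h12 * h12
        h11_last, det_last = h11, det
        converged |= np.maximum(np.abs(u1), np.abs(u2)) <= IRLS_GRAD_TOL
        active = ~converged & (det > 1e-300)
        if not active.any():
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            da = (h22 * u1 - h12 * u2) / det
            db = (h11 * u2 - h12 * u1) / det
        a = np.where(active, a + da, a)
        b = np.where(active, b + db, b)

    if not converged.all():
        logger.warning(
            "logistic scan: %d SNP(s) did not converge in %d iterations "
            "(likely separation); estimates reported at the iteration cap",
            int((~converged).sum()),
            MAX_IRLS_ITER,
        )
    # a divergent slope can still satisfy the gradient criterion (the score
    # decays exponentially along a separating direction); |log-odds| beyond
    # any biological plausibility marks those fits
    separated = np.abs(b) > 12.0
    if separated.any():
        converged = converged & ~separated
        logger.warning(
            "logistic scan: %d SNP(s) show quasi-complete separation "
            "(|log-odds| > 12); Wald statistics are unreliable there",
            int(separated.sum()),
        )
    # inverse of [[h11, h12], [h12, h22]] has slope-variance element h11/det
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b = np.where(det_last > 0, h11_last / det_last, np.inf)
    se = np.sqrt(var_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where((se > 0) & np.isfinite(se), b / se, 0.0)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR)
    return idx, b, se, p, converged


def disease_scan(data: RegionDataset) -> List[AssociationRecord]:
    """Logistic-regression disease scan: case status ~ intercept + dosage.

    Requires both classes present; monomorphic SNPs are dropped with a
    logged warning, matching the eQTL-scan policy.
    """
    if data.disease is None:
        raise ValueError("dataset has no disease phenotype")
    idx, beta, se, p, _ = logistic_scan_arrays(
        data.dosages, np.asarray(data.disease, float)
    )
    n_dropped = data.n_snps - idx.size
    if n_dropped:
        dropped = sorted(set(range(data.n_snps)) - set(idx.tolist()))
        logger.warning(
            "disease_scan: dropped %d monomorphic SNP(s): %s",
            n_dropped,
            ", ".join(data.snp_ids[j] for j in dropped),
        )
    return _records_from_arrays(data, idx, beta, se, p)


def harmonize(
    scan_disease: Sequence[AssociationRecord],
    scan_eqtl: Sequence[AssociationRecord],
) -> PairedRegionScan:
    """Align two scans onto shared SNPs with a common allele-1 orientation.

    SNPs are intersected on snp_id in the disease scan's order. Where the
    eQTL record's allele pair is the disease record's pair swapped, the
    eQTL record is flipped (beta negated, alleles exchanged); pairs that
    match neither orientation are dropped and reported.
    """
    by_id: Dict[str, AssociationRecord] = {r.snp_id: r for r in scan_eqtl}
    if len(by_id) != len(scan_eqtl):
        raise ValueError("duplicate snp_id in eQTL scan")
    seen_d = {r.snp_id for r in scan_disease}
    if len(seen_d) != len(scan_disease):
        raise ValueError("duplicate snp_id in disease scan")

    kept_d: List[AssociationRecord] = []
    kept_e: List[AssociationRecord] = []
    dropped_d: List[str] = []
    dropped_e: List[str] = [r.snp_id for r in scan_eqtl if r.snp_id not in seen_d]
    n_flipped = 0
    for rd in scan_disease:
        re_ = by_id.get(rd.snp_id)
        if re_ is None:
            dropped_d.append(rd.snp_id)
            continue
        if (re_.allele1, re_.allele2) == (rd.allele1, rd.allele2):
            pass
        elif (re_.allele2, re_.allele1) == (rd.allele1, rd.allele2):
            re_ = re_.flipped()
            n_flipped += 1
        else:
            logger.warning(
                "harmonize: %s has irreconcilable allele pairs %s/%s vs %s/%s; dropped",
                rd.snp_id, rd.allele1, rd.allele2, re_.allele1, re_.allele2,
            )
            dropped_d.append(rd.snp_id)
            dropped_e.append(rd.snp_id)
            continue
        kept_d.append(rd)
        kept_e.append(re_)
    if not kept_d:
        raise ValueError("no SNPs shared between the two scans after harmonization")
    return PairedRegionScan(
        records_disease=tuple(kept_d),
        records_eqtl=tuple(kept_e),
        n_flipped=n_flipped,
        dropped_disease=tuple(dropped_d),
        dropped_eqtl=tuple(dropped_e),
    )
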