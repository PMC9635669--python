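"""Digital-droplet PCR Poisson copy-number quantification.

In ddPCR the sample is partitioned into ~20,000 droplets; the mean
number of target molecules per droplet is recovered from the fraction
of negative droplets via lambda = -ln(negatives/total). Copy number per
haploid genome is the ratio of target lambda to a single-copy reference
lambda (daf-3 in the study this mirrors), multiplied by the dilution
factor between the two wells (target at 0.001 ng/ul vs reference at
0.1 ng/ul gives D = 100).

Droplet classification (fluorescence thresholding) is out of scope;
inputs are already-gated positive/total counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DropletWell",
    "CopyNumberEstimate",
    "lambda_from_droplets",
    "lambda_standard_error",
    "copy_number",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class DropletWell:
    """Gated droplet counts for one target in one well."""

    target: str
    positives: int
    total: int
    concentration_ng_ul: float | None = None
    droplet_volume_ul: float | None = None

    def __post_init__(self):
        if self.total <= 0:
            raise ValueError("total droplets must be positive")
        if not 0 <= self.positives <= self.total:
            raise ValueError("positives must be in [0, total]")


def lambda_from_droplets(positives: int, total: int) -> float:
    """Mean molecules per droplet from gated counts.

    lambda = -ln((total - positives)/total). A fully positive well is
    saturated and carries no concentration information.
    """
    if total <= 0:
        raise ValueError("total droplets must be positive")
    if not 0 <= positives <= total:
        raise ValueError("positives must be in [0, total]")
    if positives == total:
        raise ValueError("well saturated: all droplets positive, lambda unbounded")
    return -math.log((total - positives) / total)


def lambda_standard_error(positives: int, total: int) -> float:
    """Delta-method SE of lambda: sqrt(p / ((1 - p) n)) with p = positives/total."""
    p = positives / total
    if p >= 1:
        raise ValueError("saturated well")
    return math.sqrt(p / ((1 - p) * total))


@dataclass
class CopyNumberEstimate:
    """Target copy number per haploid genome with a 95% interval."""

    lambda_target: float
    lambda_reference: float
    dilution_factor: float
    copy_number: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not self.ci_low <= self.copy_number <= self.ci_high:
            raise ValueError("interval does not contain the point estimate")


def copy_number(target_well: DropletWell, reference_well: DropletWell,
                dilution_factor: float = 100.0) -> CopyNumberEstimate:
    """CN = (lambda_target / lambda_reference) * dilution factor.

    The dilution correction is applied multiplicatively on the lambda
    ratio (algebraically equivalent to dividing the reference-well
    positives by the dilution factor before the Poisson step). The 95%
    interval is a delta-method interval on log CN, combining the two
    wells' Poisson standard errors.
    """
    if dilution_factor <= 0:
        raise ValueError("dilution factor must be positive")
    lam_t = lambda_from_droplets(target_well.positives, target_well.total)
    lam_r = lambda_from_droplets(reference_well.positives, reference_well.total)
    if lam_r == 0:
        raise ValueError("reference lambda is zero: copy-number ratio undefined")
    cn = (lam_t / lam_r) * dilution_factor
    if lam_t == 0:
        return CopyNumberEstimate(lam_t, lam_r, dilution_factor, 0.0, 0.0, 0.0)
    se_t = lambda_standard_error(target_well.positives, target_well.total)
    se_r = lambda_standard_error(reference_well.positives, reference_well.total)
    log_se = math.sqrt((se_t / lam_t) ** 2 + (se_r / lam_r) ** 2)
    return CopyNumberEstimate(
        lambda_target=lam_t,
        lambda_reference=lam_r,
        dilution_factor=dilution_factor,
        copy_number=cn,
        ci_low=cn * math.exp(-Z_95 * log_se),
        ci_high=cn * math.exp(Z_95 * log_se),
    )
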