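"""Per-sample polygenic score: weighted risk-allele dosage sum plus APOE weight.

The score is S = sum_i d_i * w_i + w_APOE, where d_i is the risk-allele
dosage (0/1/2) at each of the five panel SNPs, w_i its per-copy weight, and
w_APOE the diplotype weight for the rs429358/rs7412 epsilon diplotype. Raw
weighted sums are reported — no centering or standardisation. With the
built-in panel the attainable range is [-0.9, 1.274].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .variant_model import (
    UNRESOLVED,
    GenotypeError,
    SampleGenotypes,
    VariantPanel,
    call_apoe_diplotype,
    risk_allele_dosage,
    validate_call,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusContribution:
    rsid: str
    dosage: Optional[int]
    weight: float

    @property
    def product(self) -> Optional[float]:
        return None if self.dosage is None else self.dosage * self.weight


@dataclass(frozen=True)
class PrsResult:
    """One sample's score with its per-locus breakdown.

    ``score`` is None when any locus is missing (default policy) and the
    ``reason`` field says which; ``complete`` is True only when all five
    dosage loci and the APOE diplotype resolved.
    """

    sample_id: str
    score: Optional[float]
    contributions: tuple[LocusContribution, ...]
    apoe_diplotype: str
    apoe_weight: Optional[float]
    complete: bool
    reason: Optional[str] = None


def compute_prs(
    sample: SampleGenotypes,
    panel: VariantPanel,
    policy: str = "default",
    allow_partial: bool = False,
) -> PrsResult:
    """Score one sample against a panel.

    By default a sample missing any of the seven loci (or with an UNRESOLVED
    APOE diplotype) gets a missing score with a structured reason. With
    ``allow_partial=True`` the available loci are summed and the result is
    flagged incomplete instead.
    """
    contributions: list[LocusContribution] = []
    missing: list[str] = []
    for vdef in panel.variants:
        call = sample.get(vdef.rsid)
        validate_call(call, panel, sample.sample_id)
        dosage = risk_allele_dosage(call, vdef)
        if dosage is None:
            missing.append(vdef.rsid)
        contributions.append(LocusContribution(vdef.rsid, dosage, vdef.weight))

    gt_a, gt_b = sample.get("rs429358"), sample.get("rs7412")
    validate_call(gt_a, panel, sample.sample_id)
    validate_call(gt_b, panel, sample.sample_id)
    diplotype = call_apoe_diplotype(gt_a, gt_b, policy=policy)
    apoe_weight = None if diplotype == UNRESOLVED else panel.apoe_weights[diplotype]
    if diplotype == UNRESOLVED:
        missing.append("APOE")

    complete = not missing
    if complete or allow_partial:
        score = sum(c.product or 0.0 for c in contributions) + (apoe_weight or 0.0)
    else:
        score = None
    reason = None if complete else "missing: " + ", ".join(missing)
    return PrsResult(
        sample_id=sample.sample_id,
        score=score,
        contributions=tuple(contributions),
        apoe_diplotype=diplotype,
        apoe_weight=apoe_weight,
        complete=complete,
        reason=reason,
    )


def score_cohort(
    samples: Iterable[SampleGenotypes],
    panel: VariantPanel,
    policy: str = "default",
    allow_partial: bool = False,
) -> list[PrsResult]:
    """Score every sample, preserving input order; duplicate IDs are fatal."""
    results: list[PrsResult] = []
    seen: set[str] = set()
    for sample in samples:
        if sample.sample_id in seen:
            raise GenotypeError(f"duplicate sample ID {sample.sample_id!r}")
        seen.add(sample.sample_id)
        results.append(compute_prs(sample, panel, policy=policy, allow_partial=allow_partial))
    n_complete = sum(r.complete for r in results)
    n_missing = sum(r.score is None for r in results)
    logger.info(
        "scored %d samples: %d complete, %d partial, %d missing",
        len(results), n_complete, len(results) - n_complete - n_missing, n_missing,
    )
    return results


def results_to_frame(results: Sequence[PrsResult], panel: VariantPanel) -> pd.DataFrame:
    """Tabulate scores: sample_id, prs, complete, apoe_diplotype, one dosage
    column per panel rsID."""
    rows = []
    for r in results:
        row: dict = {
            "sample_id": r.sample_id,
            "prs": r.score,
            "complete": r.complete,
            "apoe_diplotype": r.apoe_diplotype,
        }
        for c in r.contributions:
            row[f"dosage_{c.rsid}"] = c.dosage
        rows.append(row)
    return pd.DataFrame(rows)


def score_dosage_matrix(
    dosages: np.ndarray,
    diplotypes: Sequence[str],
    panel: VariantPanel,
) -> np.ndarray:
    """Vectorised scoring for simulation-scale inputs.

    ``dosages`` is an (n, 5) integer array of risk-allele dosages ordered as
    ``panel.panel_rsids``; ``diplotypes`` the per-sample APOE diplotype
    labels. Equivalent to :func:`compute_prs` sample by sample.
    """
    dosages = np.asarray(dosages)
    if dosages.ndim != 2 or dosages.shape[1] != len(panel.variants):
        raise ValueError(f"dosage matrix must be (n, {len(panel.variants)})")
    weights = np.array([v.weight for v in panel.variants])
    apoe = np.array([panel.apoe_weights[d] for d in diplotypes])
    return dosages @ weights + apoe
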