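"""Seeded two-group cohort simulator: HWE genotypes plus phenotype tables.

Emulates a STEMI patient group (n=93) and a high-LDL comparison group (n=61)
with the per-group variant-allele frequencies, LDL-C medians/ranges, and
covariate prevalences reported for the study cohorts. Loci are simulated
independently (no LD) except rs429358/rs7412, whose haplotypes are drawn
jointly from epsilon-allele frequencies under a no-e1 constraint. Genotypes
at each locus follow Hardy-Weinberg proportions (two independent allele
draws). Optionally, case status is assigned by a logistic disease model on
the polygenic score and smoking, and group quotas are filled by rejection.

All randomness flows from one ``numpy.random.default_rng`` seed; per-group
and per-stage draws happen in a fixed order so identical configs reproduce
byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .prs_engine import score_dosage_matrix
from .variant_model import (
    GenotypeCall,
    SampleGenotypes,
    VariantPanel,
    load_builtin_panel,
)

#: Variant-allele frequencies per group (fraction, not percent). The variant
#: allele is the HGVS alternate at each site; for rs6511720 and rs1800562
#: this is the *protective* minor allele, not the risk allele.
DEFAULT_PATIENT_FREQS = {
    "rs6511720": 0.1613,
    "rs1800562": 0.04301,
    "rs629301": 0.7527,
    "rs11220462": 0.4301,
    "rs1367117": 0.5699,
    "rs7412": 0.1505,
    "rs429358": 0.2258,
}

DEFAULT_COMPARISON_FREQS = {
    "rs6511720": 0.3607,
    "rs1800562": 0.0492,
    "rs629301": 0.5574,
    "rs11220462": 0.2623,
    "rs1367117": 0.5902,
    "rs7412": 0.1967,
    "rs429358": 0.1639,
}


@dataclass(frozen=True)
class GroupPhenotypeParams:
    """Marginal phenotype distributions for one group.

    LDL-C (mmol/L) is drawn log-normally, matched to the configured median
    and truncated to the configured min-max range; binary covariates are
    Bernoulli at the configured prevalences; age is uniform on its range.
    """

    ldl_median: float
    ldl_range: tuple[float, float]
    male_frac: float
    smoking: float
    statin: float
    hypertension: float
    age_range: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.ldl_range
        if not (0 < lo <= self.ldl_median <= hi):
            raise ValueError("LDL-C median must lie inside its positive range")
        for name in ("male_frac", "smoking", "statin", "hypertension"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


DEFAULT_PATIENT_PHENOTYPES = GroupPhenotypeParams(
    ldl_median=3.88, ldl_range=(2.87, 6.63),
    male_frac=0.516, smoking=0.591, statin=0.312, hypertension=0.516,
    age_range=(42, 96),
)

DEFAULT_COMPARISON_PHENOTYPES = GroupPhenotypeParams(
    ldl_median=5.67, ldl_range=(3.19, 9.7),
    male_frac=0.557, smoking=0.279, statin=0.049, hypertension=0.75,
    age_range=(45, 72),
)


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic case-assignment model: logit P(case) = intercept
    + beta_prs * PRS + beta_smoking * smoking."""

    intercept: float
    beta_prs: float
    beta_smoking: float


@dataclass
class CohortConfig:
    n_patients: int = 93
    n_comparison: int = 61
    patient_freqs: dict = field(default_factory=lambda: dict(DEFAULT_PATIENT_FREQS))
    comparison_freqs: dict = field(default_factory=lambda: dict(DEFAULT_COMPARISON_FREQS))
    #: "allele" treats configured frequencies as allele frequencies;
    #: "carrier" converts a carrier frequency c to 1 - sqrt(1 - c) first.
    freq_kind: str = "allele"
    patient_phenotypes: GroupPhenotypeParams = DEFAULT_PATIENT_PHENOTYPES
    comparison_phenotypes: GroupPhenotypeParams = DEFAULT_COMPARISON_PHENOTYPES
    disease_model: Optional[DiseaseModel] = None
    panel_name: str = "futema2015_modified"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_comparison < 1:
            raise ValueError("group sizes must be >= 1")
        if self.freq_kind not in ("allele", "carrier"):
            raise ValueError(f"freq_kind must be 'allele' or 'carrier', got {self.freq_kind!r}")
        for freqs in (self.patient_freqs, self.comparison_freqs):
            for rsid, f in freqs.items():
                if not 0 <= f <= 1:
                    raise ValueError(f"{rsid}: frequency {f} outside [0, 1]")


@dataclass
class SyntheticCohort:
    genotypes: list[SampleGenotypes]
    phenotypes: pd.DataFrame
    provenance: dict

    def __post_init__(self) -> None:
        geno_ids = {s.sample_id for s in self.genotypes}
        pheno_ids = set(self.phenotypes["sample_id"])
        if geno_ids != pheno_ids:
            raise ValueError("genotype and phenotype tables must share one sample_id set")


def carrier_to_allele_freq(carrier: float) -> float:
    """Convert a carrier frequency (>=1 copy) to an allele frequency under HWE."""
    if not 0 <= carrier <= 1:
        raise ValueError(f"carrier frequency {carrier} outside [0, 1]")
    return 1.0 - math.sqrt(1.0 - carrier)


def simulate_genotypes(freq: float, n: int, rng: np.random.Generator | int) -> np.ndarray:
    """Draw n variant-allele dosages (0/1/2) at one locus under HWE.

    Each dosage is the sum of two independent allele draws at frequency
    ``freq``, giving genotype class proportions (1-p)^2, 2p(1-p), p^2.
    """
    if not 0 <= freq <= 1:
        raise ValueError(f"allele frequency {freq} outside [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.binomial(2, freq, size=n)


def simulate_apoe_haplotypes(
    freq_429358_c: float, freq_7412_t: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n pairs of epsilon haplotypes from the two marginal variant-allele
    frequencies under the no-e1 constraint.

    e4 frequency = f(rs429358-C), e2 frequency = f(rs7412-T), e3 the rest.
    Returns two (n, 2) arrays of per-haplotype alleles at rs429358 and rs7412.
    """
    p_e4, p_e2 = freq_429358_c, freq_7412_t
    p_e3 = 1.0 - p_e4 - p_e2
    if p_e3 < 0:
        raise ValueError("rs429358-C and rs7412-T frequencies sum above 1; no e3 mass left")
    haps = rng.choice(3, size=(n, 2), p=[p_e2, p_e3, p_e4])  # 0=e2, 1=e3, 2=e4
    allele_429358 = np.where(haps == 2, "C", "T")
    allele_7412 = np.where(haps == 0, "T", "C")
    return allele_429358, allele_7412


def _effective_freqs(freqs: dict, freq_kind: str) -> dict:
    if freq_kind == "carrier":
        return {rsid: carrier_to_allele_freq(f) for rsid, f in freqs.items()}
    return dict(freqs)


def simulate_group_arrays(
    freqs: dict,
    n: int,
    rng: np.random.Generator,
    panel: VariantPanel,
    freq_kind: str = "allele",
) -> dict:
    """Vectorised genotype draw for one group.

    Returns arrays: per-panel-SNP variant dosage and risk dosage (n, 5),
    APOE per-haplotype alleles, and diplotype labels. The diplotype label is
    derived from the drawn haplotypes directly (no e1 is ever simulated, so
    it always agrees with the default unphased-calling policy).
    """
    eff = _effective_freqs(freqs, freq_kind)
    variant_dosage = np.column_stack(
        [simulate_genotypes(eff[rsid], n, rng) for rsid in panel.panel_rsids]
    )
    risk_is_alt = np.array(
        [v.risk_allele == panel.loci[v.rsid].alt for v in panel.variants]
    )
    risk_dosage = np.where(risk_is_alt, variant_dosage, 2 - variant_dosage)
    hap_429358, hap_7412 = simulate_apoe_haplotypes(
        eff["rs429358"], eff["rs7412"], n, rng
    )
    eps = np.where(hap_429358 == "C", "e4", np.where(hap_7412 == "T", "e2", "e3"))
    eps.sort(axis=1)
    diplotypes = np.char.add(eps[:, 0], eps[:, 1])
    return {
        "variant_dosage": variant_dosage,
        "risk_dosage": risk_dosage,
        "hap_429358": hap_429358,
        "hap_7412": hap_7412,
        "diplotypes": diplotypes,
    }


def simulate_prs_and_smoking(
    freqs: dict,
    smoking_prev: float,
    n: int,
    rng: np.random.Generator,
    panel: Optional[VariantPanel] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast path for power/recovery studies: per-sample PRS and smoking flag
    drawn at the given frequencies, without building genotype objects."""
    panel = panel or load_builtin_panel("futema2015_modified")
    arrays = simulate_group_arrays(freqs, n, rng, panel)
    prs = score_dosage_matrix(arrays["risk_dosage"], arrays["diplotypes"], panel)
    smoking = rng.random(n) < smoking_prev
    return prs, smoking.astype(int)


def _truncated_lognormal(
    median: float, lo: float, hi: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Right-skewed LDL-C draw: log-normal with exp(mu) = median, sigma set
    so the configured range spans the central 99% of the untruncated law,
    then rejection-truncated to [lo, hi]."""
    mu = math.log(median)
    z99 = 2.5758293035489004  # 99.5th standard-normal percentile
    sigma = max((math.log(hi) - math.log(lo)) / (2 * z99), 1e-6)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=max(n - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _group_phenotypes(
    params: GroupPhenotypeParams,
    n: int,
    rng: np.random.Generator,
    smoking: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    lo, hi = params.age_range
    return pd.DataFrame(
        {
            "sex": np.where(rng.random(n) < params.male_frac, "M", "F"),
            "age": rng.integers(lo, hi + 1, size=n),
            "ldl_c": np.round(
                _truncated_lognormal(params.ldl_median, *params.ldl_range, n, rng), 2
            ),
            "smoking": smoking if smoking is not None
            else (rng.random(n) < params.smoking).astype(int),
            "statin": (rng.random(n) < params.statin).astype(int),
            "hypertension": (rng.random(n) < params.hypertension).astype(int),
        }
    )


def _genotype_objects(
    sample_ids: list[str], arrays: dict, panel: VariantPanel
) -> list[SampleGenotypes]:
    samples = []
    specs = [panel.loci[rsid] for rsid in panel.panel_rsids]
    for i, sid in enumerate(sample_ids):
        sg = SampleGenotypes(sid)
        for j, spec in enumerate(specs):
            d = int(arrays["variant_dosage"][i, j])
            alleles = [spec.ref] * (2 - d) + [spec.alt] * d
            sg.add(GenotypeCall(spec.rsid, alleles[0], alleles[1]))
        sg.add(GenotypeCall("rs429358", *sorted(arrays["hap_429358"][i])))
        sg.add(GenotypeCall("rs7412", *sorted(arrays["hap_7412"][i])))
        samples.append(sg)
    return samples


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


_MAX_DISEASE_DRAWS = 1_000_000


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a two-group cohort per the config.

    Without a disease model, each group's genotypes are drawn at its own
    allele frequencies. With a disease model, candidates are drawn from the
    comparison-group frequencies and smoking prevalence, case status is
    Bernoulli at sigmoid(intercept + b_prs*PRS + b_smoke*smoking), and the
    two group quotas are filled from cases and controls respectively.
    """
    panel = load_builtin_panel(config.panel_name)
    rng = np.random.default_rng(config.seed)
    pat_ids = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    cmp_ids = [f"C{i + 1:03d}" for i in range(config.n_comparison)]

    if config.disease_model is None:
        pat_arrays = simulate_group_arrays(
            config.patient_freqs, config.n_patients, rng, panel, config.freq_kind
        )
        cmp_arrays = simulate_group_arrays(
            config.comparison_freqs, config.n_comparison, rng, panel, config.freq_kind
        )
        pat_pheno = _group_phenotypes(config.patient_phenotypes, config.n_patients, rng)
        cmp_pheno = _group_phenotypes(config.comparison_phenotypes, config.n_comparison, rng)
    else:
        dm = config.disease_model
        need_case, need_ctrl = config.n_patients, config.n_comparison
        kept_case: list[dict] = []
        kept_ctrl: list[dict] = []
        drawn = 0
        batch = 4 * (need_case + need_ctrl)
        while (len(kept_case) < need_case or len(kept_ctrl) < need_ctrl):
            if drawn >= _MAX_DISEASE_DRAWS:
                raise RuntimeError(
                    f"disease-model quota unsatisfiable within {_MAX_DISEASE_DRAWS} draws; "
                    f"got {len(kept_case)}/{need_case} cases, {len(kept_ctrl)}/{need_ctrl} controls"
                )
            arrays = simulate_group_arrays(
                config.comparison_freqs, batch, rng, panel, config.freq_kind
            )
            smoking = (rng.random(batch) < config.comparison_phenotypes.smoking).astype(int)
            prs = score_dosage_matrix(arrays["risk_dosage"], arrays["diplotypes"], panel)
            p_case = _sigmoid(dm.intercept + dm.beta_prs * prs + dm.beta_smoking * smoking)
            is_case = rng.random(batch) < p_case
            drawn += batch
            for i in range(batch):
                bucket = kept_case if is_case[i] else kept_ctrl
                quota = need_case if is_case[i] else need_ctrl
                if len(bucket) < quota:
                    bucket.append(
                        {
                            "variant_dosage": arrays["variant_dosage"][i],
                            "hap_429358": arrays["hap_429358"][i],
                            "hap_7412": arrays["hap_7412"][i],
                            "smoking": int(smoking[i]),
                        }
                    )

        def _stack(rows: list[dict]) -> dict:
            return {
                "variant_dosage": np.array([r["variant_dosage"] for r in rows]),
                "hap_429358": np.array([r["hap_429358"] for r in rows]),
                "hap_7412": np.array([r["hap_7412"] for r in rows]),
            }

        pat_arrays, cmp_arrays = _stack(kept_case), _stack(kept_ctrl)
        pat_pheno = _group_phenotypes(
            config.patient_phenotypes, need_case, rng,
            smoking=np.array([r["smoking"] for r in kept_case]),
        )
        cmp_pheno = _group_phenotypes(
            config.comparison_phenotypes, need_ctrl, rng,
            smoking=np.array([r["smoking"] for r in kept_ctrl]),
        )

    pat_pheno.insert(0, "sample_id", pat_ids)
    pat_pheno.insert(1, "group", "patient")
    cmp_pheno.insert(0, "sample_id", cmp_ids)
    cmp_pheno.insert(1, "group", "comparison")
    phenotypes = pd.concat([pat_pheno, cmp_pheno], ignore_index=True)

    genotypes = _genotype_objects(pat_ids, pat_arrays, panel) + _genotype_objects(
        cmp_ids, cmp_arrays, panel
    )
    provenance = {
        "config": _config_dict(config),
        "seed": config.seed,
        "n_samples": len(genotypes),
    }
    return SyntheticCohort(genotypes=genotypes, phenotypes=phenotypes, provenance=provenance)


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    for key in ("patient_phenotypes", "comparison_phenotypes"):
        d[key] = {k: list(v) if isinstance(v, tuple) else v for k, v in d[key].items()}
    return d
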