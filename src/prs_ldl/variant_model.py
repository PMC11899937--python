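"""SNP panel definitions, genotype representation, allele dosage, and APOE diplotype calling.

The LDL-C SNP score combines seven loci: five SNPs scored additively on
risk-allele dosage (``rs629301``/*CELSR2*, ``rs1367117``/*APOB*,
``rs11220462``/*ST3GAL4*, ``rs6511720``/*LDLR*, ``rs1800562``/*HFE*) and the
two *APOE* coding SNPs ``rs429358`` and ``rs7412``, which jointly define the
classical epsilon haplotypes (e2, e3, e4) and are weighted only at the
diplotype level.

Two of the dosage-weighted loci (``rs6511720`` and ``rs1800562``) have the
*reference* allele as the risk allele: the minor alleles at those sites are
LDL-lowering, so the common homozygote carries two weighted copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

NUCLEOTIDES = frozenset("ACGT")

#: APOE epsilon-haplotype definitions as (rs429358 allele, rs7412 allele).
#: e1 (C, T) falls outside the three-allele system handled here.
EPSILON_HAPLOTYPES = {
    ("T", "T"): "e2",
    ("T", "C"): "e3",
    ("C", "C"): "e4",
    ("C", "T"): "e1",
}

#: The six resolvable APOE diplotypes, in increasing order of score weight.
APOE_DIPLOTYPES = ("e2e2", "e2e3", "e2e4", "e3e3", "e3e4", "e4e4")

UNRESOLVED = "unresolved"


class PanelError(ValueError):
    """A variant panel is malformed or an unknown panel was requested."""


class GenotypeError(ValueError):
    """A genotype call is inconsistent with the declared allele set."""


@dataclass(frozen=True)
class VariantDef:
    """One dosage-weighted SNP: its risk allele and per-copy score weight.

    ``reference_allele`` may equal ``risk_allele``: the weight then applies
    to copies of the major/reference allele.
    """

    rsid: str
    gene: str
    reference_allele: str
    risk_allele: str
    weight: float

    def __post_init__(self) -> None:
        for allele in (self.reference_allele, self.risk_allele):
            if allele not in NUCLEOTIDES:
                raise PanelError(f"{self.rsid}: allele {allele!r} is not one of A/C/G/T")
        if not (self.weight == self.weight and abs(self.weight) != float("inf")):
            raise PanelError(f"{self.rsid}: weight must be finite")


@dataclass(frozen=True)
class AlleleSpec:
    """Locus metadata: declared reference/alternate alleles and a GRCh38
    coordinate used only when emitting VCF (matching is always rsID-based)."""

    rsid: str
    ref: str
    alt: str
    chrom: str
    pos: int

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset((self.ref, self.alt))


@dataclass(frozen=True)
class ApoeWeightTable:
    """Score weight per APOE diplotype (e2e2 ... e4e4)."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if tuple(self.weights) != APOE_DIPLOTYPES:
            raise PanelError(
                f"APOE weight table must contain exactly {APOE_DIPLOTYPES} in order, "
                f"got {tuple(self.weights)}"
            )
        vals = list(self.weights.values())
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise PanelError("APOE diplotype weights must be strictly increasing e2e2 -> e4e4")
        if self.weights["e3e3"] != 0:
            raise PanelError("e3e3 is the neutral diplotype; its weight must be 0")

    def __getitem__(self, diplotype: str) -> float:
        return self.weights[diplotype]


@dataclass(frozen=True)
class GenotypeCall:
    """An unphased biallelic genotype at one rsID; both alleles present or
    both missing (no half-calls)."""

    rsid: str
    allele_1: Optional[str]
    allele_2: Optional[str]

    def __post_init__(self) -> None:
        if (self.allele_1 is None) != (self.allele_2 is None):
            raise GenotypeError(f"{self.rsid}: half-calls are not allowed")
        for allele in (self.allele_1, self.allele_2):
            if allele is not None and allele not in NUCLEOTIDES:
                raise GenotypeError(f"{self.rsid}: allele {allele!r} is not one of A/C/G/T")

    @property
    def is_missing(self) -> bool:
        return self.allele_1 is None

    @property
    def alleles(self) -> tuple[str, str]:
        if self.is_missing:
            raise GenotypeError(f"{self.rsid}: genotype is missing")
        return (self.allele_1, self.allele_2)  # type: ignore[return-value]

    @classmethod
    def missing(cls, rsid: str) -> "GenotypeCall":
        return cls(rsid, None, None)


@dataclass
class SampleGenotypes:
    """All genotype calls for one sample, keyed by rsID (at most one each)."""

    sample_id: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def add(self, call: GenotypeCall) -> None:
        if call.rsid in self.calls:
            raise GenotypeError(f"sample {self.sample_id}: duplicate call for {call.rsid}")
        self.calls[call.rsid] = call

    def get(self, rsid: str) -> GenotypeCall:
        """Return the call for ``rsid``, or a MISSING call if absent."""
        return self.calls.get(rsid, GenotypeCall.missing(rsid))


@dataclass(frozen=True)
class VariantPanel:
    """The scoring panel: five dosage-weighted SNPs, the APOE diplotype
    weight table, and allele/coordinate metadata for all seven loci."""

    name: str
    version: str
    variants: tuple[VariantDef, ...]
    apoe_weights: ApoeWeightTable
    loci: Mapping[str, AlleleSpec]

    @property
    def panel_rsids(self) -> tuple[str, ...]:
        return tuple(v.rsid for v in self.variants)

    @property
    def all_rsids(self) -> tuple[str, ...]:
        return self.panel_rsids + ("rs429358", "rs7412")

    def variant(self, rsid: str) -> VariantDef:
        for v in self.variants:
            if v.rsid == rsid:
                return v
        raise PanelError(f"{rsid} is not a dosage-weighted panel SNP")

    def allele_set(self, rsid: str) -> frozenset[str]:
        try:
            return self.loci[rsid].allele_set
        except KeyError:
            raise PanelError(f"{rsid} is not in panel {self.name!r}") from None


# Built-in panel: the 2015 six-SNP LDL gene score adapted to melt-based
# genotyping (rs6544713 swapped for rs11220462 and rs1800562 added).
_FUTEMA_VARIANTS = (
    VariantDef("rs629301", "CELSR2", "G", "T", 0.15),
    VariantDef("rs1367117", "APOB", "G", "A", 0.1),
    VariantDef("rs11220462", "ST3GAL4", "G", "A", 0.05),
    VariantDef("rs6511720", "LDLR", "G", "G", 0.18),
    VariantDef("rs1800562", "HFE", "G", "G", 0.057),
)

_FUTEMA_APOE = ApoeWeightTable(
    {
        "e2e2": -0.9,
        "e2e3": -0.4,
        "e2e4": -0.2,
        "e3e3": 0.0,
        "e3e4": 0.1,
        "e4e4": 0.2,
    }
)

# GRCh38 coordinates are panel metadata for VCF emission only.
_FUTEMA_LOCI = {
    "rs629301": AlleleSpec("rs629301", "G", "T", "1", 109275684),
    "rs1367117": AlleleSpec("rs1367117", "G", "A", "2", 21044073),
    "rs11220462": AlleleSpec("rs11220462", "G", "A", "11", 126374652),
    "rs6511720": AlleleSpec("rs6511720", "G", "T", "19", 11091630),
    "rs1800562": AlleleSpec("rs1800562", "G", "A", "6", 26092913),
    "rs429358": AlleleSpec("rs429358", "T", "C", "19", 44908684),
    "rs7412": AlleleSpec("rs7412", "C", "T", "19", 44908822),
}

_BUILTIN_PANELS = {
    "futema2015_modified": VariantPanel(
        name="futema2015_modified",
        version="1",
        variants=_FUTEMA_VARIANTS,
        apoe_weights=_FUTEMA_APOE,
        loci=_FUTEMA_LOCI,
    )
}


def load_builtin_panel(panel_name: str) -> VariantPanel:
    """Return a built-in scoring panel by name.

    Raises :class:`PanelError` naming the available panels if unknown.
    """
    try:
        return _BUILTIN_PANELS[panel_name]
    except KeyError:
        available = ", ".join(sorted(_BUILTIN_PANELS))
        raise PanelError(
            f"unknown panel {panel_name!r}; available panels: {available}"
        ) from None


def validate_call(call: GenotypeCall, panel: VariantPanel, sample_id: str = "?") -> None:
    """Check a non-missing call against the panel's declared allele set."""
    if call.is_missing:
        return
    allowed = panel.allele_set(call.rsid)
    for allele in call.alleles:
        if allele not in allowed:
            raise GenotypeError(
                f"sample {sample_id}, {call.rsid}: allele {allele!r} not in "
                f"declared allele set {{{'/'.join(sorted(allowed))}}}"
            )


def risk_allele_dosage(call: GenotypeCall, vdef: VariantDef) -> Optional[int]:
    """Count copies of the variant's risk allele in an unphased call.

    Returns 0, 1, or 2; ``None`` if the genotype is missing. Symmetric in
    allele order. Alleles outside the variant's {reference, risk} declaration
    are validated upstream against the panel allele set; here any allele not
    equal to the risk allele simply contributes zero copies.
    """
    if call.rsid != vdef.rsid:
        raise GenotypeError(f"call for {call.rsid} scored against variant {vdef.rsid}")
    if call.is_missing:
        return None
    return sum(1 for a in call.alleles if a == vdef.risk_allele)


def call_apoe_diplotype(
    gt_429358: GenotypeCall,
    gt_7412: GenotypeCall,
    policy: str = "default",
) -> str:
    """Call the APOE diplotype from unphased rs429358 and rs7412 genotypes.

    Haplotypes: e2 = (rs429358-T, rs7412-T), e3 = (T, C), e4 = (C, C).
    The doubly heterozygous genotype (T/C, C/T) is phase-ambiguous between
    e2/e4 and e1/e3; since e1 is vanishingly rare the conventional call is
    e2e4 (``policy="default"``); ``policy="strict"`` returns UNRESOLVED
    instead. Genotypes consistent only with e1-bearing phasings raise
    :class:`GenotypeError`.

    Missing genotype at either site returns UNRESOLVED.
    """
    if policy not in ("default", "strict"):
        raise ValueError(f"unknown APOE resolution policy {policy!r}")
    if gt_429358.rsid != "rs429358" or gt_7412.rsid != "rs7412":
        raise GenotypeError("call_apoe_diplotype expects calls for rs429358 and rs7412")
    if gt_429358.is_missing or gt_7412.is_missing:
        return UNRESOLVED
    for call, allowed in ((gt_429358, {"T", "C"}), (gt_7412, {"C", "T"})):
        for allele in call.alleles:
            if allele not in allowed:
                raise GenotypeError(
                    f"{call.rsid}: allele {allele!r} not in declared set {{C/T}}"
                )

    a1, a2 = gt_429358.alleles
    b1, b2 = gt_7412.alleles
    # Two possible phasings of the unphased pair of genotypes.
    phasings = {
        tuple(sorted((EPSILON_HAPLOTYPES[(a1, b1)], EPSILON_HAPLOTYPES[(a2, b2)]))),
        tuple(sorted((EPSILON_HAPLOTYPES[(a1, b2)], EPSILON_HAPLOTYPES[(a2, b1)]))),
    }
    valid = sorted(p for p in phasings if "e1" not in p)
    if not valid:
        raise GenotypeError(
            "diplotype outside e2/e3/e4 system (requires an e1 haplotype: "
            "rs429358-C with rs7412-T in cis)"
        )
    ambiguous = len(valid) < len(phasings)
    if ambiguous and policy == "strict":
        return UNRESOLVED
    hap_a, hap_b = valid[0]
    return hap_a + hap_b
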