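"""Population-genetic statistics on larva-level karyotype genotype tables.

The unit of observation is a larva scored at a set of named rearrangements,
each genotype being standard homozygote (``S/S``), heterozygote (``S/I``) or
inverted homozygote (``I/I``).  Frequencies are per chromosomal homologue
(two per larva).  The module covers homologue frequencies, the uncorrected
Pearson chi-square goodness-of-fit test for Hardy-Weinberg equilibrium at
df = 1, per-larva autosomal heterozygosity, co-carriage of linked inversion
pairs, a sex-linkage heuristic, and the assembly of per-cytoform rearrangement
profiles (role + frequency per rearrangement).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy import stats

from .arms import Registry
from .errors import (
    EmptySampleError,
    InconsistencyError,
    MonomorphicError,
    SexDataUnavailableError,
    UndefinedPercentageError,
)

logger = logging.getLogger(__name__)

GENOTYPES = ("S/S", "S/I", "I/I")
MISSING = "-"

# Profile roles
ABSENT = "absent"
POLYMORPHIC = "polymorphic"
FIXED = "fixed"
X_LINKED = "X-linked"
Y_LINKED = "Y-linked"
ROLES = (ABSENT, POLYMORPHIC, FIXED, X_LINKED, Y_LINKED)


@dataclass(frozen=True)
class GenotypeCount:
    """Collapsed genotype counts at one rearrangement (ss, si, ii)."""

    n_ss: int
    n_si: int
    n_ii: int

    def __post_init__(self) -> None:
        if min(self.n_ss, self.n_si, self.n_ii) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_ss + self.n_si + self.n_ii


@dataclass
class LarvaRecord:
    """One larva: collection site, sex, genotypes, optional karyotype flags."""

    larva_id: str
    site_id: str
    sex: str  # "female" | "male"
    genotypes: dict[str, str] = field(default_factory=dict)
    sex_constitution: str | None = None
    b_chromosome: bool = False
    mermithid: bool = False


@dataclass
class RoleCall:
    """Role of one rearrangement within a cytoform profile."""

    role: str
    frequency: float | None = None  # per-homologue; None for absent / no data

    def is_present(self) -> bool:
        return self.role != ABSENT


@dataclass
class CytoformProfile:
    """Per-rearrangement roles for one cytoform (one column of a survey table)."""

    cytoform_id: str
    roles: dict[str, RoleCall] = field(default_factory=dict)

    def fixed_set(self) -> frozenset[str]:
        return frozenset(r for r, c in self.roles.items() if c.role == FIXED)

    def present_set(self) -> frozenset[str]:
        return frozenset(r for r, c in self.roles.items() if c.is_present())


@dataclass
class HweResult:
    """Uncorrected Pearson chi-square HWE goodness-of-fit result (df = 1)."""

    chi2: float
    df: int
    p_value: float
    expected: tuple[float, float, float]
    low_expected_warning: bool


@dataclass
class SexLinkageResult:
    call: str  # "autosomal" | "Y-linked-candidate" | "X-linked-candidate"
    carriers_by_sex: dict[str, int]
    noncarriers_by_sex: dict[str, int]
    fisher_p: float
    low_evidence: bool


def collapse_genotypes(larvae: Iterable[LarvaRecord], rid: str) -> GenotypeCount:
    """Collapse a larva table to (ss, si, ii) counts at one rearrangement.

    Larvae missing or unscored at the locus are excluded from the denominator.
    """
    counts = {g: 0 for g in GENOTYPES}
    for larva in larvae:
        g = larva.genotypes.get(rid, MISSING)
        if g in counts:
            counts[g] += 1
    return GenotypeCount(counts["S/S"], counts["S/I"], counts["I/I"])


def allele_frequency(gc: GenotypeCount) -> float:
    """Per-homologue frequency of the rearranged arrangement:
    ``(si + 2*ii) / (2*n)``."""
    if gc.n == 0:
        raise EmptySampleError("no scored larvae")
    return (gc.n_si + 2 * gc.n_ii) / (2 * gc.n)


def hwe_chisq(gc: GenotypeCount) -> HweResult:
    """Pearson chi-square goodness of fit against Hardy-Weinberg proportions.

    Expectations are ``n*(1-p)^2, 2n*p*(1-p), n*p^2`` with ``p`` the observed
    homologue frequency; no continuity correction; df = 1 (three genotype
    classes minus one estimated allele frequency).  Expected counts below 1
    attach a warning but do not block the test.

    Raises
    ------
    MonomorphicError
        If the sample is monomorphic (p = 0 or 1); the test is undefined.
    """
    p = allele_frequency(gc)
    if p == 0.0 or p == 1.0:
        raise MonomorphicError("monomorphic sample: HWE test undefined")
    n = gc.n
    expected = (n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2)
    observed = (gc.n_ss, gc.n_si, gc.n_ii)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    low = any(e < 1.0 for e in expected)
    if low:
        warnings.warn(
            f"HWE test with expected count < 1 (expected={expected}); "
            "chi-square approximation is unreliable",
            stacklevel=2,
        )
    return HweResult(chi2=chi2, df=1, p_value=p_value, expected=expected,
                     low_expected_warning=low)


def mean_autosomal_heterozygosity(
    larvae: list[LarvaRecord],
    registry: Registry,
    roles: CytoformProfile,
) -> float:
    """Mean number of heterozygous autosomal inversions per larva.

    Autosomal polymorphic loci are those with role ``polymorphic`` in the
    profile (sex-linked and fixed rearrangements are excluded).  Missing
    genotypes are excluded from the numerator only, with a warning.
    """
    if not larvae:
        raise EmptySampleError("empty larva list")
    loci = [
        rid
        for rid, call in roles.roles.items()
        if call.role == POLYMORPHIC and registry.resolve(rid).kind == "inversion"
    ]
    het = 0
    missing = 0
    for larva in larvae:
        for rid in loci:
            g = larva.genotypes.get(rid, MISSING)
            if g == "S/I":
                het += 1
            elif g not in GENOTYPES:
                missing += 1
    if missing:
        warnings.warn(
            f"{missing} missing genotype(s) excluded from heterozygosity numerator",
            stacklevel=2,
        )
    return het / len(larvae)


def _is_carrier(genotype: str) -> bool:
    return genotype in ("S/I", "I/I")


def co_carriage(
    larvae: Iterable[LarvaRecord], locus_a: str, locus_b: str
) -> tuple[int, int, float]:
    """Carrier overlap of two loci: (n_either, n_both, percent both, 1 dp).

    A carrier holds at least one rearranged homologue (``S/I`` or ``I/I``).
    """
    n_either = 0
    n_both = 0
    for larva in larvae:
        a = _is_carrier(larva.genotypes.get(locus_a, MISSING))
        b = _is_carrier(larva.genotypes.get(locus_b, MISSING))
        if a or b:
            n_either += 1
        if a and b:
            n_both += 1
    if n_either == 0:
        raise UndefinedPercentageError(
            f"no larva carries {locus_a} or {locus_b}; percentage undefined"
        )
    return n_either, n_both, round(100.0 * n_both / n_either, 1)


def intersection_from_counts(carriers_a: int, carriers_b: int, n_either: int) -> int:
    """Inclusion-exclusion: carriers of both loci from marginal and union counts."""
    if not (max(carriers_a, carriers_b) <= n_either <= carriers_a + carriers_b):
        raise InconsistencyError(
            f"union {n_either} inconsistent with marginals "
            f"{carriers_a}, {carriers_b}"
        )
    return carriers_a + carriers_b - n_either


def detect_sex_linkage(
    larvae: list[LarvaRecord], rid: str, *, alpha: float = 0.05
) -> SexLinkageResult:
    """Heuristic sex-linkage call for one rearrangement, with evidence.

    * ``Y-linked-candidate``: every carrier is male, every male carrier is
      heterozygous, no female carries it, and the carrier-by-sex association
      is significant (Fisher exact p < alpha).
    * ``X-linked-candidate``: carriage significantly female-associated, or
      male carriers are never inverted-homozygous while inverted-homozygous
      females exist (hemizygous X pattern), with a significant association
      required for the frequency-based route.
    * otherwise ``autosomal``; sparse evidence (< 2 carriers or a
      non-significant table) is flagged ``low_evidence``.

    The call is heuristic: published role assignments, made from direct
    chromosome pairing observations, should be supplied as overrides to
    :func:`build_profile` where available.
    """
    if any(larva.sex not in ("female", "male") for larva in larvae):
        raise SexDataUnavailableError("larval sexes missing or unreadable")
    car = {"female": 0, "male": 0}
    non = {"female": 0, "male": 0}
    male_hom = male_het = female_hom = 0
    for larva in larvae:
        g = larva.genotypes.get(rid, MISSING)
        if g not in GENOTYPES:
            continue
        if _is_carrier(g):
            car[larva.sex] += 1
            if larva.sex == "male":
                male_het += g == "S/I"
                male_hom += g == "I/I"
            elif g == "I/I":
                female_hom += 1
        else:
            non[larva.sex] += 1
    n_car = car["female"] + car["male"]
    if n_car == 0:
        raise EmptySampleError(f"no carriers of {rid}")
    table = [[car["male"], non["male"]], [car["female"], non["female"]]]
    fisher_p = float(stats.fisher_exact(table)[1])
    low_evidence = n_car < 2 or fisher_p >= alpha
    call = "autosomal"
    if fisher_p < alpha:
        if car["female"] == 0 and male_hom == 0 and car["male"] > 0:
            call = "Y-linked-candidate"
        elif car["female"] > car["male"] or (male_hom == 0 and female_hom > 0):
            call = "X-linked-candidate"
    elif male_hom == 0 and female_hom > 0 and car["male"] > 0:
        # hemizygosity pattern: males carry only heterozygously
        call = "X-linked-candidate"
        low_evidence = False
    return SexLinkageResult(
        call=call,
        carriers_by_sex=car,
        noncarriers_by_sex=non,
        fisher_p=fisher_p,
        low_evidence=low_evidence,
    )


def build_profile(
    larvae: list[LarvaRecord],
    registry: Registry,
    cytoform_id: str = "cytoform",
    overrides: Mapping[str, str] | None = None,
) -> CytoformProfile:
    """Assemble a cytoform profile (role + frequency per rearrangement).

    Per rearrangement scored in the table: the per-homologue frequency is
    computed over scored larvae; role ``fixed`` iff frequency 1.0, ``absent``
    iff 0.0, otherwise ``polymorphic`` unless the sex-linkage heuristic
    promotes it.  ``overrides`` (rearrangement id -> role) always win and are
    logged, carrying the published observational role assignments.
    """
    if not larvae:
        raise EmptySampleError("empty larva list")
    overrides = dict(overrides or {})
    loci = sorted({rid for larva in larvae for rid in larva.genotypes})
    for rid in loci:
        registry.resolve(rid)  # raises RegistryError for unknown ids
    sexes_known = all(larva.sex in ("female", "male") for larva in larvae)
    profile = CytoformProfile(cytoform_id=cytoform_id)
    for rid in loci:
        gc = collapse_genotypes(larvae, rid)
        freq = allele_frequency(gc) if gc.n else None
        if freq is None or freq == 0.0:
            call = RoleCall(ABSENT, None)
        elif freq == 1.0:
            call = RoleCall(FIXED, 1.0)
        else:
            role = POLYMORPHIC
            if sexes_known:
                sl = detect_sex_linkage(larvae, rid)
                if sl.call == "Y-linked-candidate":
                    role = Y_LINKED
                elif sl.call == "X-linked-candidate":
                    role = X_LINKED
            call = RoleCall(role, freq)
        if rid in overrides:
            logger.info(
                "role override for %s/%s: %s -> %s",
                cytoform_id, rid, call.role, overrides[rid],
            )
            call = RoleCall(overrides[rid], call.frequency)
        profile.roles[rid] = call
    for rid, role in overrides.items():
        if rid not in profile.roles:
            registry.resolve(rid)
            logger.info("role override for %s/%s: (unscored) -> %s",
                        cytoform_id, rid, role)
            profile.roles[rid] = RoleCall(role, None)
    return profile
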