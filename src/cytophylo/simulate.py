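"""Synthetic larva-level karyotype datasets.

Emulates the sampling design of a cytoform survey: each simulated larva gets
a sex, autosomal genotypes drawn from Hardy-Weinberg proportions at specified
per-homologue frequencies (optionally perturbed by an inbreeding-style
coefficient ``hwe_deviation``: positive values deplete heterozygotes,
negative values inflate them), fixed rearrangements always inverted-
homozygous, and sex-linked rearrangements realized mechanistically through
explicit X/Y chromosome variants each carrying a set of inversions — so
downstream sex-linkage detection has a faithful test bed rather than per-sex
frequency shortcuts.  B-chromosome and mermithid flags are independent
Bernoulli draws carried only so record schemas round-trip; no biology is
modeled behind them.

:func:`simulate_clade` layers populations on a gains tree for end-to-end
topology-recovery testing; :func:`make_reference_fixtures` (re-exported from
:mod:`cytophylo.reference`) rebuilds the published survey tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arms import Registry
from .errors import SimulationSpecError
from .popgen import (
    CytoformProfile,
    FIXED,
    POLYMORPHIC,
    RoleCall,
    X_LINKED,
    Y_LINKED,
    LarvaRecord,
)
from .reference import make_reference_fixtures  # noqa: F401  (re-export)

__all__ = [
    "ChromosomeVariant",
    "SexSystem",
    "SimulationSpec",
    "simulate_population",
    "GainNode",
    "simulate_clade",
    "make_reference_fixtures",
]


@dataclass(frozen=True)
class ChromosomeVariant:
    """One X or Y variant: a name, the inversions it carries, its frequency."""

    name: str
    inversions: frozenset[str]
    frequency: float


@dataclass
class SexSystem:
    """Sex-chromosome system: X and Y variant pools with frequencies.

    Females draw two X variants independently; males draw one X and one Y.
    A larva's genotype at a sex-linked rearrangement is S/S, S/I or I/I
    according to how many of its sex chromosomes carry that inversion.
    """

    x_variants: list[ChromosomeVariant]
    y_variants: list[ChromosomeVariant]

    def __post_init__(self) -> None:
        for pool, label in ((self.x_variants, "X"), (self.y_variants, "Y")):
            if not pool:
                raise SimulationSpecError(f"empty {label}-variant pool")
            total = sum(v.frequency for v in pool)
            if abs(total - 1.0) > 1e-9:
                raise SimulationSpecError(
                    f"{label}-variant frequencies sum to {total}, expected 1"
                )

    def linked_loci(self) -> frozenset[str]:
        return frozenset().union(
            *(v.inversions for v in self.x_variants + self.y_variants)
        )


@dataclass
class SimulationSpec:
    """Study conditions for one simulated cytoform population."""

    cytoform_id: str
    n_larvae: int
    profile: CytoformProfile
    seed: int
    sex_ratio: float = 0.5  # probability female
    sex_system: SexSystem | None = None
    hwe_deviation: float = 0.0
    b_chromosome_rate: float = 0.0
    mermithid_rate: float = 0.0
    site_id: str = "sim"

    def validate(self, registry: Registry | None = None) -> None:
        if self.n_larvae < 0:
            raise SimulationSpecError("n_larvae must be non-negative")
        for name, value in (
            ("sex_ratio", self.sex_ratio),
            ("b_chromosome_rate", self.b_chromosome_rate),
            ("mermithid_rate", self.mermithid_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise SimulationSpecError(f"{name}={value} outside [0, 1]")
        if not -1.0 <= self.hwe_deviation <= 1.0:
            raise SimulationSpecError(
                f"hwe_deviation={self.hwe_deviation} outside [-1, 1]"
            )
        for rid, call in self.profile.roles.items():
            if call.role == POLYMORPHIC:
                if call.frequency is None or not 0.0 <= call.frequency <= 1.0:
                    raise SimulationSpecError(
                        f"{rid}: polymorphic role needs a frequency in [0, 1]"
                    )
            if call.role in (X_LINKED, Y_LINKED) and self.sex_system is None:
                raise SimulationSpecError(
                    f"{rid}: sex-linked role requires a sex_system"
                )
            if registry is not None:
                registry.resolve(rid)
        if registry is not None and self.sex_system is not None:
            for rid in self.sex_system.linked_loci():
                registry.resolve(rid)


def _genotype_probs(p: float, f: float) -> np.ndarray:
    """HWE genotype probabilities at homologue frequency ``p`` with
    inbreeding-style deviation ``f`` (positive = heterozygote deficit)."""
    q = 1.0 - p
    probs = np.array(
        [q * q + f * p * q, 2.0 * p * q * (1.0 - f), p * p + f * p * q]
    )
    probs = np.clip(probs, 0.0, None)
    total = probs.sum()
    if total <= 0:
        raise SimulationSpecError(f"degenerate genotype distribution at p={p}, f={f}")
    return probs / total


_GENOTYPES = np.array(["S/S", "S/I", "I/I"])


def simulate_population(
    spec: SimulationSpec, registry: Registry | None = None
) -> list[LarvaRecord]:
    """Draw one larva table under ``spec``; deterministic given the seed."""
    spec.validate(registry)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_larvae
    if n == 0:
        return []
    sexes = np.where(rng.random(n) < spec.sex_ratio, "female", "male")

    sex_loci = spec.sex_system.linked_loci() if spec.sex_system else frozenset()
    larvae = [
        LarvaRecord(
            larva_id=f"{spec.cytoform_id}-{i + 1:03d}",
            site_id=spec.site_id,
            sex=str(sexes[i]),
            b_chromosome=bool(rng.random() < spec.b_chromosome_rate),
            mermithid=bool(rng.random() < spec.mermithid_rate),
        )
        for i in range(n)
    ]

    for rid, call in sorted(spec.profile.roles.items()):
        if rid in sex_loci or call.role in (X_LINKED, Y_LINKED):
            continue  # realized through chromosome variants below
        if call.role == FIXED:
            for larva in larvae:
                larva.genotypes[rid] = "I/I"
        elif call.role == POLYMORPHIC:
            draws = rng.choice(
                _GENOTYPES, size=n, p=_genotype_probs(call.frequency, spec.hwe_deviation)
            )
            for larva, g in zip(larvae, draws):
                larva.genotypes[rid] = str(g)
        # absent roles are simply not scored

    if spec.sex_system is not None:
        xs = spec.sex_system.x_variants
        ys = spec.sex_system.y_variants
        xp = np.array([v.frequency for v in xs])
        yp = np.array([v.frequency for v in ys])
        for larva in larvae:
            first = xs[rng.choice(len(xs), p=xp)]
            if larva.sex == "female":
                second = xs[rng.choice(len(xs), p=xp)]
            else:
                second = ys[rng.choice(len(ys), p=yp)]
            larva.sex_constitution = f"{first.name}{second.name}"
            for rid in sorted(sex_loci):
                dose = (rid in first.inversions) + (rid in second.inversions)
                larva.genotypes[rid] = _GENOTYPES[dose]
    return larvae


@dataclass
class GainNode:
    """Node of a gains tree: rearrangements gained on the branch leading in."""

    name: str
    gains: list[str] = field(default_factory=list)
    children: list["GainNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


def simulate_clade(
    tree: GainNode,
    tip_specs: dict[str, SimulationSpec],
    registry: Registry | None = None,
) -> dict[str, list[LarvaRecord]]:
    """Simulate one population per tip of a gains tree.

    Characters gained on the path from the root to a tip are fixed (frequency
    1.0) at that tip unless its spec already assigns them a role (e.g. kept
    polymorphic).  A tip spec that declares a gained character absent is
    inconsistent and rejected.  Profile recovery followed by matrix building
    and cladogram inference recovers the generating topology whenever every
    internal edge carries at least one gained character.
    """
    out: dict[str, list[LarvaRecord]] = {}

    def walk(node: GainNode, acc: tuple[str, ...]) -> None:
        acc = acc + tuple(node.gains)
        if node.is_tip:
            try:
                spec = tip_specs[node.name]
            except KeyError:
                raise SimulationSpecError(f"no SimulationSpec for tip {node.name!r}")
            merged = CytoformProfile(cytoform_id=spec.cytoform_id)
            merged.roles.update(spec.profile.roles)
            for rid in acc:
                call = merged.roles.get(rid)
                if call is None:
                    merged.roles[rid] = RoleCall(FIXED, 1.0)
                elif not call.is_present() or (
                    call.role == POLYMORPHIC and not call.frequency
                ):
                    raise SimulationSpecError(
                        f"tip {node.name!r}: gained character {rid} declared "
                        f"{call.role} with frequency {call.frequency}"
                    )
            eff = SimulationSpec(
                cytoform_id=spec.cytoform_id,
                n_larvae=spec.n_larvae,
                profile=merged,
                seed=spec.seed,
                sex_ratio=spec.sex_ratio,
                sex_system=spec.sex_system,
                hwe_deviation=spec.hwe_deviation,
                b_chromosome_rate=spec.b_chromosome_rate,
                mermithid_rate=spec.mermithid_rate,
                site_id=spec.site_id,
            )
            out[node.name] = simulate_population(eff, registry)
        else:
            for child in node.children:
                walk(child, acc)

    walk(tree, ())
    return out
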