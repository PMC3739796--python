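"""Tabular readers/writers and pipeline orchestration.

All tabular formats are UTF-8 TSV with mandatory headers and ``#`` comments;
trees are newick.  Machine-facing coordinates are 0-based half-open
throughout.  :func:`run_pipeline` ties the stages together in dependency
order (simulate -> profile/hwe -> derive -> tree) and emits a machine-
readable run report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .arms import Registry, read_arrangement_file, read_registry
from .errors import CytophyloError, FormatError, RegistryError
from .phylogeny import build_character_matrix, infer_cladogram, write_newick
from .popgen import (
    GENOTYPES,
    MISSING,
    ROLES,
    CytoformProfile,
    LarvaRecord,
    RoleCall,
    allele_frequency,
    build_profile,
    collapse_genotypes,
    hwe_chisq,
)
from .scenarios import constrained_scenarios

logger = logging.getLogger(__name__)

_META_COLUMNS = ["larva_id", "site", "sex", "b_chromosome", "mermithid"]
_OPT_COLUMNS = ["sex_constitution"]


def read_genotype_table(
    path: str | Path, registry: Registry | None = None
) -> list[LarvaRecord]:
    """Read a larva genotype TSV.

    Columns: ``larva_id, site, sex, b_chromosome, mermithid`` (and optionally
    ``sex_constitution``), then one column per rearrangement id with values
    ``S/S``, ``S/I``, ``I/I`` or ``-``.  Malformed rows are collected into a
    single :class:`FormatError` naming line numbers; unknown rearrangement
    columns raise :class:`RegistryError` when a registry is supplied.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing_meta = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise FormatError(f"{path}: missing header column(s) {missing_meta}")
    locus_cols = [c for c in df.columns if c not in _META_COLUMNS + _OPT_COLUMNS]
    if registry is not None:
        unknown = [c for c in locus_cols if c not in registry]
        if unknown:
            raise RegistryError(f"{path}: unknown rearrangement column(s) {unknown}")
    records: list[LarvaRecord] = []
    problems: list[str] = []
    valid = set(GENOTYPES) | {MISSING}
    for row_idx, row in df.iterrows():
        lineno = row_idx + 2  # header is line 1
        if row["sex"] not in ("female", "male"):
            problems.append(f"line {lineno}: bad sex {row['sex']!r}")
        genotypes = {}
        for c in locus_cols:
            v = row[c].strip()
            if v not in valid:
                problems.append(f"line {lineno}: bad genotype {v!r} in column {c}")
            genotypes[c] = v
        records.append(
            LarvaRecord(
                larva_id=row["larva_id"],
                site_id=row["site"],
                sex=row["sex"],
                genotypes=genotypes,
                sex_constitution=(row.get("sex_constitution") or None),
                b_chromosome=row["b_chromosome"].lower() in ("1", "true", "yes"),
                mermithid=row["mermithid"].lower() in ("1", "true", "yes"),
            )
        )
    if problems:
        raise FormatError(f"{path}: " + "; ".join(problems))
    return records


def write_genotype_table(path: str | Path, larvae: list[LarvaRecord]) -> None:
    loci = sorted({rid for l in larvae for rid in l.genotypes})
    with_sc = any(l.sex_constitution for l in larvae)
    columns = _META_COLUMNS + (["sex_constitution"] if with_sc else []) + loci
    rows = []
    for l in larvae:
        row = {
            "larva_id": l.larva_id,
            "site": l.site_id,
            "sex": l.sex,
            "b_chromosome": str(l.b_chromosome).lower(),
            "mermithid": str(l.mermithid).lower(),
        }
        if with_sc:
            row["sex_constitution"] = l.sex_constitution or ""
        for rid in loci:
            row[rid] = l.genotypes.get(rid, MISSING)
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> dict[str, CytoformProfile]:
    """Read a long-format profile TSV (cytoform, rearrangement, role,
    frequency)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    need = ["cytoform", "rearrangement", "role", "frequency"]
    if list(df.columns) != need:
        raise FormatError(f"{path}: expected columns {need}, found {list(df.columns)}")
    out: dict[str, CytoformProfile] = {}
    for _, row in df.iterrows():
        if row["role"] not in ROLES:
            raise FormatError(f"{path}: unknown role {row['role']!r}")
        prof = out.setdefault(row["cytoform"], CytoformProfile(row["cytoform"]))
        if row["rearrangement"] == "-":  # placeholder for a role-less profile
            continue
        freq = float(row["frequency"]) if row["frequency"] else None
        prof.roles[row["rearrangement"]] = RoleCall(row["role"], freq)
    return out


def write_profiles(path: str | Path, profiles) -> None:
    """Write profiles in long format; frequencies rendered at 2 decimals to
    mirror the published survey table (full precision is an in-memory
    concern)."""
    rows = []
    for prof in profiles:
        if not prof.roles:
            # keep rearrangement-free profiles (e.g. the outgroup) readable
            rows.append(
                {"cytoform": prof.cytoform_id, "rearrangement": "-",
                 "role": "absent", "frequency": ""}
            )
        for rid, call in sorted(prof.roles.items()):
            rows.append(
                {
                    "cytoform": prof.cytoform_id,
                    "rearrangement": rid,
                    "role": call.role,
                    "frequency": "" if call.frequency is None else f"{call.frequency:.2f}",
                }
            )
    pd.DataFrame(rows, columns=["cytoform", "rearrangement", "role", "frequency"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class RunConfig:
    """Declarative description of one reproducible pipeline run."""

    out_dir: str
    seed: int | None = None
    arrangements: str | None = None
    registry: str | None = None
    genotype_tables: dict[str, str] = field(default_factory=dict)  # cytoform -> path
    profiles: str | None = None
    # stage toggles + parameters
    hwe: list[dict] = field(default_factory=list)  # {cytoform, locus, site?}
    profile: bool = False
    derive: dict | None = None  # {source, target, observed: [names], limit?}
    tree: dict | None = None  # {outgroup}
    simulate: dict | None = None  # reserved for spec-file driven simulation
    max_arrangement_length: int = 20
    max_depth: int = 6
    limit: int = 1000
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("arrangements", "registry", "profiles"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FormatError(f"config: {name} path {p} does not exist")
        for cyto, p in self.genotype_tables.items():
            if not Path(p).exists():
                raise FormatError(f"config: genotype table {cyto}={p} does not exist")
        if min(self.max_arrangement_length, self.max_depth, self.limit) <= 0:
            raise FormatError("config: caps must be positive")
        if self.simulate is not None and self.seed is None:
            raise FormatError("config: seed required when simulation is enabled")


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the run report.

    The report records package version, seed, input digests and per-stage
    summaries, and is also written as ``run_report.json`` in the output
    directory.  Any stage error is recorded and re-raised after the report is
    written.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "inputs": {},
        "stages": {},
        "errors": [],
    }
    for name in ("arrangements", "registry", "profiles"):
        p = getattr(config, name)
        if p:
            report["inputs"][name] = {"path": str(p), "sha256": _digest(p)}
    for cyto, p in config.genotype_tables.items():
        report["inputs"][f"genotypes_{cyto}"] = {"path": str(p), "sha256": _digest(p)}

    registry = read_registry(config.registry) if config.registry else None
    tables = {
        cyto: read_genotype_table(path, registry)
        for cyto, path in config.genotype_tables.items()
    }

    try:
        if config.hwe:
            results = []
            for req in config.hwe:
                larvae = tables[req["cytoform"]]
                if req.get("site"):
                    larvae = [l for l in larvae if l.site_id == str(req["site"])]
                gc = collapse_genotypes(larvae, req["locus"])
                res = hwe_chisq(gc)
                results.append(
                    {
                        "cytoform": req["cytoform"],
                        "locus": req["locus"],
                        "site": req.get("site"),
                        "n": gc.n,
                        "frequency": round(allele_frequency(gc), 2),
                        "chi2": round(res.chi2, 2),
                        "df": res.df,
                        "p_value": round(res.p_value, 4),
                    }
                )
            pd.DataFrame(results).to_csv(out / "hwe.tsv", sep="\t", index=False)
            report["stages"]["hwe"] = {"n_tests": len(results), "results": results}

        profiles: dict[str, CytoformProfile] = {}
        if config.profile and tables:
            for cyto, larvae in tables.items():
                profiles[cyto] = build_profile(larvae, registry, cytoform_id=cyto)
            write_profiles(out / "profiles.tsv", profiles.values())
            report["stages"]["profile"] = {"cytoforms": sorted(profiles)}
        elif config.profiles:
            profiles = read_profiles(config.profiles)

        if config.derive:
            arr = read_arrangement_file(config.arrangements)
            source = arr[config.derive["source"]]
            target = arr[config.derive["target"]]
            observed = {n: arr[n] for n in config.derive.get("observed", [])}
            res = constrained_scenarios(
                source, target, observed,
                limit=config.derive.get("limit", config.limit),
                max_length=config.max_arrangement_length,
                max_depth=config.max_depth,
            )
            rows = []
            for rank, sc in enumerate(res.scenarios, start=1):
                rows.append(
                    {
                        "rank": rank,
                        "steps": ";".join(f"[{i},{j})" for i, j in sc.windows()),
                        "observed_hits": sc.observed_hits,
                        "matched_names": ",".join(m or "-" for m in sc.matched_names),
                        "hypothetical_count": sc.hypothetical_count,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "scenarios.tsv", sep="\t", index=False)
            top = res.scenarios[0] if res.scenarios else None
            report["stages"]["derive"] = {
                "n_scenarios": len(res.scenarios),
                "truncated": res.truncated,
                "optimum_unique": res.optimum_unique,
                "top_observed_hits": top.observed_hits if top else None,
                "top_windows": list(top.windows()) if top else None,
            }

        if config.tree:
            if not profiles:
                raise FormatError("tree stage needs profiles (stage or file)")
            matrix = build_character_matrix(
                list(profiles.values()), outgroup_id=config.tree["outgroup"]
            )
            clad = infer_cladogram(matrix)
            newick = write_newick(clad)
            (out / "tree.nwk").write_text(newick + "\n")
            syn_rows = [
                {"node": ",".join(sorted(n.taxa)), "character": c}
                for n in clad.root.walk()
                for c in n.synapomorphies
            ]
            pd.DataFrame(syn_rows, columns=["node", "character"]).to_csv(
                out / "synapomorphies.tsv", sep="\t", index=False
            )
            report["stages"]["tree"] = {
                "newick": newick,
                "n_conflicting": sum(
                    1 for s in clad.character_status.values() if s == "conflicting"
                ),
            }
    except CytophyloError as exc:
        report["errors"].append(str(exc))
        (out / "run_report.json").write_text(json.dumps(report, indent=2))
        raise

    (out / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
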