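"""Readers and writers for the tabular dataset formats.

All formats are plain CSV/YAML/JSON:

* linkage map:   ``chromosome,marker,position_cM``
* genotypes:     ``individual,origin,<marker...>`` with absolute codes
                 2 = P1/P1, 1 = het, 0 = P2/P2, empty = missing;
                 origin is ``BC_P1`` or ``BC_P2``
* phenotypes:    ``environment,individual,value`` (trait units)
* scenario:      YAML mirroring :class:`bcqtl.simulate.QtlScenario`
* results:       JSON (positions, effects, thresholds, config echo)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import (
    EpistasisEffect,
    LinkageMap,
    ProgenyData,
    QtlEffect,
    QtlScenario,
)

__all__ = [
    "write_map", "read_map",
    "write_genotypes", "read_genotypes",
    "write_phenotypes", "read_phenotypes",
    "write_scenario", "read_scenario",
    "write_dataset", "read_dataset",
    "write_result",
]

ORIGIN_LABELS = {0: "BC_P1", 1: "BC_P2"}


def write_map(lmap: LinkageMap, path) -> None:
    lmap.to_frame().to_csv(path, index=False)


def read_map(path) -> LinkageMap:
    df = pd.read_csv(path)
    required = {"chromosome", "marker", "position_cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: linkage map must have columns {sorted(required)}")
    try:
        return LinkageMap.from_frame(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_genotypes(data: ProgenyData, path) -> None:
    names = [m for chrom in data.lmap.marker_names for m in chrom]
    df = pd.DataFrame(data.genotypes.astype(float), columns=names)
    df = df.where(df >= 0, np.nan)
    df.insert(0, "origin", [ORIGIN_LABELS[o] for o in data.origin])
    df.insert(0, "individual", np.arange(1, data.n_individuals + 1))
    df.to_csv(path, index=False, float_format="%.0f")


def read_genotypes(path, lmap: LinkageMap):
    df = pd.read_csv(path)
    for col in ("individual", "origin"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["individual"].duplicated().any():
        dup = df.loc[df["individual"].duplicated(), "individual"].iloc[0]
        raise ValueError(f"{path}: duplicate individual id {dup!r}")
    names = [m for chrom in lmap.marker_names for m in chrom]
    missing = set(names) - set(df.columns)
    extra = set(df.columns) - set(names) - {"individual", "origin"}
    if missing or extra:
        raise ValueError(
            f"{path}: marker columns do not match the linkage map "
            f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
        )
    bad = set(df["origin"]) - set(ORIGIN_LABELS.values())
    if bad:
        raise ValueError(f"{path}: unknown origin labels {sorted(bad)}")
    origin = (df["origin"] == "BC_P2").to_numpy(dtype=np.int8)
    geno = df[names].to_numpy(dtype=float)
    codes = np.where(np.isnan(geno), -1, geno)
    if not np.isin(codes, (-1, 0, 1, 2)).all():
        raise ValueError(f"{path}: genotype codes must be 0/1/2 or missing")
    return codes.astype(np.int8), origin, df["individual"].to_numpy()


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"environment", "individual", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: phenotypes must have columns {sorted(required)}")
    if df.duplicated(["environment", "individual"]).any():
        raise ValueError(f"{path}: duplicate (environment, individual) record")
    return df.dropna(subset=["value"]).reset_index(drop=True)


def write_scenario(scenario: QtlScenario, path) -> None:
    d = {
        "n_env": scenario.n_env,
        "heritability": scenario.heritability,
        "mu": scenario.mu,
        "sigma2_env": scenario.sigma2_env,
        "qtls": [dataclasses.asdict(q) for q in scenario.qtls],
        "epistasis": [dataclasses.asdict(e) for e in scenario.epistasis],
    }
    for q in d["qtls"]:
        q["ae"], q["de"] = list(q["ae"]), list(q["de"])
    for e in d["epistasis"]:
        e["aae"] = list(e["aae"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_scenario(path) -> QtlScenario:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    try:
        return QtlScenario(
            qtls=[QtlEffect(**q) for q in d["qtls"]],
            epistasis=[EpistasisEffect(**e) for e in d.get("epistasis", [])],
            n_env=d["n_env"],
            heritability=d["heritability"],
            mu=d.get("mu", 0.0),
            sigma2_env=d.get("sigma2_env", 0.0),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid scenario file: {exc}") from exc


def write_dataset(data: ProgenyData, outdir, scenario: QtlScenario | None = None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_map(data.lmap, outdir / "map.csv")
    write_genotypes(data, outdir / "genotypes.csv")
    if data.phenotypes is not None:
        write_phenotypes(data.phenotypes, outdir / "phenotypes.csv")
    if scenario is not None:
        write_scenario(scenario, outdir / "scenario.yaml")
    return outdir


def read_dataset(map_path, geno_path, pheno_path, line_type: str = "DH") -> ProgenyData:
    """Load and cross-validate a dataset from its three CSV files."""
    lmap = read_map(map_path)
    codes, origin, individuals = read_genotypes(geno_path, lmap)
    pheno = read_phenotypes(pheno_path)
    known = set(individuals)
    unknown = set(pheno["individual"]) - known
    if unknown:
        raise ValueError(
            f"{pheno_path}: phenotype individuals not in genotype file: "
            f"{sorted(unknown)[:5]}"
        )
    try:
        return ProgenyData(
            lmap=lmap, genotypes=codes, origin=origin,
            line_type=line_type.upper(), phenotypes=pheno,
        )
    except ValueError as exc:
        raise ValueError(f"{geno_path}: {exc}") from exc


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        v = float(x)
        return v if np.isfinite(v) else None
    if isinstance(x, float) and not np.isfinite(x):
        return None
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_result(result, outdir, n_env: int = 3) -> Path:
    """MappingResult -> result.json + profile/effect CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "qtls": _jsonable(result.qtls),
        "pairs": _jsonable(result.pairs),
        "thresholds": _jsonable(result.thresholds),
        "cofactors": _jsonable(list(result.cofactors)),
        "cofactor_pairs": _jsonable([list(p) for p in result.cofactor_pairs]),
        "audit": list(result.audit),
        "config": _jsonable(result.config),
    }
    if result.posterior is not None:
        payload["variance_components"] = _jsonable(result.posterior.variance_components)
        result.posterior.effects.to_csv(outdir / "effects.csv", index=False)
        payload["main_effects"] = _jsonable(
            result.main_effects_table(n_env).to_dict("records")
        )
        payload["epistasis_effects"] = _jsonable(
            result.epistasis_table(n_env).to_dict("records")
        )
    with open(outdir / "result.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    for kind, prof in getattr(result, "profiles", {}).items():
        prof.table.to_csv(outdir / f"profile_{kind}.csv", index=False)
    return outdir / "result.json"
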