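"""File formats: expression tables, parameter files, run configuration.

All data files are tab-separated text with ``#``-prefixed comment headers,
in the tradition of FlyEx-era columnar tools.  Every file written by the
package starts with metadata comment lines (version, seed, config hash).
Run configuration is YAML with fixed sections (model / space / es / sa /
run); unknown keys are rejected to catch typos early.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import model as M
from .es import ESConfig
from .objective import ExpressionDataSet, ParameterLayout, SearchSpace
from .sa import SAConfig

__all__ = [
    "RunConfig",
    "ModelSection",
    "RunSection",
    "read_expression_table",
    "write_expression_table",
    "read_parameters",
    "write_parameters",
    "read_config",
    "write_config",
    "metadata_header",
]

VERSION = "0.1.0"
_META_COLUMNS = ["time_class", "nucleus_index", "ap_position_percent", "bcd"]


def metadata_header(seed: int | None = None, config_hash: str | None = None,
                    extra: dict | None = None) -> list[str]:
    lines = [f"gencircuit {VERSION}"]
    if seed is not None:
        lines.append(f"seed: {seed}")
    if config_hash is not None:
        lines.append(f"config_hash: {config_hash}")
    for k, v in (extra or {}).items():
        lines.append(f"{k}: {v}")
    return lines


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def write_expression_table(path, data: ExpressionDataSet,
                           header_lines: list[str] | None = None) -> None:
    """Write a FlyEx-style tab-separated expression table."""
    path = Path(path)
    cols = _META_COLUMNS + list(data.genes)
    with open(path, "w") as fh:
        for line in header_lines or metadata_header():
            fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for _, row in data.table[cols].iterrows():
            cells = []
            for c in cols:
                v = row[c]
                if c == "nucleus_index":
                    cells.append(str(int(v)))
                elif pd.isna(v):
                    cells.append("NA")
                else:
                    cells.append(f"{v:.10g}")
            fh.write("\t".join(cells) + "\n")


def read_expression_table(path) -> ExpressionDataSet:
    """Read a FlyEx-style table, validating every row.

    Errors carry 1-based line numbers.  Gene maxima are recomputed from the
    parsed table; the Bcd profile of each division epoch is reconstructed
    from the per-row bcd column (epochs are identified by nucleus count
    relative to the earliest time class).
    """
    path = Path(path)
    header = None
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                missing = [c for c in _META_COLUMNS if c not in header]
                if missing:
                    raise ValueError(
                        f"{path}:{lineno}: missing required columns {missing}")
                continue
            if len(cells) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"got {len(cells)}")
            rec = {}
            for col, cell in zip(header, cells):
                if cell == "NA":
                    rec[col] = np.nan
                    continue
                try:
                    rec[col] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: cannot parse {cell!r} in column "
                        f"{col!r}") from None
            rec["nucleus_index"] = int(rec["nucleus_index"])
            genes = [c for c in header if c not in _META_COLUMNS]
            for g in genes:
                if not np.isnan(rec[g]) and rec[g] < 0:
                    raise ValueError(
                        f"{path}:{lineno}: negative concentration for {g}")
            rows.append(rec)
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    genes = tuple(c for c in header if c not in _META_COLUMNS)
    table = pd.DataFrame(rows)
    # Reconstruct per-epoch Bcd profiles from nucleus counts.
    counts = table.groupby("time_class")["nucleus_index"].count()
    n0 = int(counts.iloc[0])
    bcd_by_epoch = {}
    for t, n in counts.items():
        epoch = int(round(np.log2(n / n0)))
        if epoch not in bcd_by_epoch:
            sub = table[table["time_class"] == t].sort_values("nucleus_index")
            bcd_by_epoch[epoch] = sub["bcd"].to_numpy()
    return ExpressionDataSet(table=table, genes=genes,
                             bcd_by_epoch=bcd_by_epoch)


# ---------------------------------------------------------------------------
# Parameter files
# ---------------------------------------------------------------------------


def write_parameters(path, params: M.GeneCircuitParams, space: SearchSpace,
                     header_lines: list[str] | None = None) -> None:
    """Write a circuit as a two-column (name, value) TSV."""
    from .objective import pack_parameters

    theta = pack_parameters(params, space)
    with open(path, "w") as fh:
        for line in header_lines or metadata_header():
            fh.write(f"# {line}\n")
        fh.write("name\tvalue\n")
        fh.write(f"n_genes\t{params.n_genes}\n")
        genes = params.gene_names()
        fh.write("genes\t" + ",".join(genes) + "\n")
        hf = theta.layout.h_fixed_value
        fh.write(f"h_fixed\t{'' if hf is None else hf}\n")
        fh.write("h_free\t" + ",".join(str(int(x)) for x in theta.layout.h_free) + "\n")
        for name, value in zip(theta.layout.param_names(), theta.values):
            fh.write(f"{name}\t{value:.12g}\n")


def read_parameters(path) -> M.GeneCircuitParams:
    """Read a circuit parameter TSV written by :func:`write_parameters`."""
    meta = {}
    values = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line == "name\tvalue":
                continue
            name, _, value = line.partition("\t")
            if name in ("n_genes", "genes", "h_fixed", "h_free"):
                meta[name] = value
            else:
                values[name] = float(value)
    ng = int(meta["n_genes"])
    genes = tuple(meta["genes"].split(","))
    h_fixed = float(meta["h_fixed"]) if meta.get("h_fixed") else None
    h_free = tuple(bool(int(x)) for x in meta["h_free"].split(","))
    layout = ParameterLayout(n_genes=ng, h_free=h_free, h_fixed_value=h_fixed,
                             genes=genes)
    vec = np.array([values[n] for n in layout.param_names()])
    return layout.unpack(vec)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSection:
    n_genes: int = 6
    solver_tol: float = 1e-3
    solver_method: str = "bulirsch-stoer"
    sigmoid: str = "default"


@dataclass(frozen=True)
class RunSection:
    mode: str = "serial"
    n_islands: int = 1
    seed: int = 0
    termination: str = "fixed_generations"
    threshold: float | None = None
    hold: int = 1
    log_dir: str = "logs"


@dataclass(frozen=True)
class RunConfig:
    """All settings of one optimisation run, in named sections.

    Defaults are the published gap-gene operating point (lambda=125, mu=25,
    chi=0.85, P_f=0.45, alpha=0.2, phi*=1, migration every 200, logging
    every 20, Lambda=1e-4, h=-2.5, 40000 generations).
    """

    model: ModelSection = field(default_factory=ModelSection)
    space: SearchSpace = field(default_factory=SearchSpace)
    es: ESConfig = field(default_factory=ESConfig)
    sa: SAConfig = field(default_factory=SAConfig)
    run: RunSection = field(default_factory=RunSection)

    def config_hash(self) -> str:
        text = yaml.safe_dump(_to_dict(self), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


_SECTIONS = {"model": ModelSection, "space": SearchSpace, "es": ESConfig,
             "sa": SAConfig, "run": RunSection}


def _to_dict(config: RunConfig) -> dict:
    out = {}
    for name in _SECTIONS:
        section = getattr(config, name)
        d = asdict(section)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        out[name] = d
    return out


def _from_dict(data: dict) -> RunConfig:
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if section is None:
            section = {}
        allowed = {f.name for f in fields(cls)}
        unknown = set(section) - allowed
        if unknown:
            raise ValueError(
                f"unknown keys in [{name}]: {sorted(unknown)}")
        coerced = {}
        for f in fields(cls):
            if f.name not in section:
                continue
            v = section[f.name]
            if isinstance(v, list):
                v = tuple(v)
            coerced[f.name] = v
        try:
            kwargs[name] = cls(**coerced)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid [{name}] section: {exc}") from exc
    return RunConfig(**kwargs)


def write_config(path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gencircuit {VERSION} run configuration\n")
        yaml.safe_dump(_to_dict(config), fh, sort_keys=False)


def read_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping of sections")
    return _from_dict(data)
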