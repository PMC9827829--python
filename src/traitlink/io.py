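"""Configuration files, TSV tables, and population snapshots.

All tables are tab-separated text with a header row.  Missing values are
written as ``NA``.  Numeric output is rounded to 6 significant digits for
diffability unless full precision is requested.

The population snapshot format is one row per chromosome::

    individual  sex  habitat  chromosome  alleles

where ``alleles`` is a string of L single-character codes: ``A``/``B``
for the trait alleles A/A' at position 0, and ``w`` (wild type), ``p``
(preference for AA), ``q`` (preference for A'A'), ``n`` (neutral marker)
at positions 1..L-1.  The generation counter is kept in a ``# generation=``
comment on the first line, so a snapshot round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ModelParams, Population, SITE_CHARS, TRAIT_CHARS

_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_CONFIG_KEYS = {"out_dir", "snapshot_generations", "replicates", "log_level"}

_TRAIT_DECODE = {v: k for k, v in TRAIT_CHARS.items()}
_SITE_DECODE = {v: k for k, v in SITE_CHARS.items()}
_SEX_CHARS = {0: "F", 1: "M"}
_HAB_CHARS = {0: "H1", 1: "H2"}


@dataclass(frozen=True)
class RunConfig:
    """A validated run configuration: model parameters plus run plumbing."""

    params: ModelParams = field(default_factory=ModelParams)
    out_dir: str | None = None
    snapshot_generations: tuple[int, ...] = ()
    replicates: int = 1
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(g < 0 for g in self.snapshot_generations):
            raise ValueError("snapshot generations must be >= 0")


def config_from_mapping(data: dict) -> RunConfig:
    """Build a RunConfig from a flat mapping; unknown keys are rejected."""
    data = dict(data or {})
    unknown = set(data) - _PARAM_KEYS - _CONFIG_KEYS
    if unknown:
        raise ValueError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))}"
        )
    param_kwargs = {k: data[k] for k in _PARAM_KEYS & set(data)}
    cfg_kwargs = {k: data[k] for k in _CONFIG_KEYS & set(data)}
    if "snapshot_generations" in cfg_kwargs:
        cfg_kwargs["snapshot_generations"] = tuple(
            int(g) for g in cfg_kwargs["snapshot_generations"]
        )
    return RunConfig(params=ModelParams(**param_kwargs), **cfg_kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; an empty file yields all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    try:
        return config_from_mapping(data)
    except (ValueError, TypeError) as err:
        raise ValueError(f"invalid config {path}: {err}") from None


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config so that :func:`load_config` round-trips it."""
    data = dataclasses.asdict(cfg.params)
    data.update(
        out_dir=cfg.out_dir,
        snapshot_generations=list(cfg.snapshot_generations),
        replicates=cfg.replicates,
        log_level=cfg.log_level,
    )
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


# --- tables -------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, full_precision: bool = False,
                index: bool = True) -> None:
    """Write a DataFrame as TSV (NA for missing; 6 significant digits
    unless ``full_precision``)."""
    fmt = None if full_precision else "%.6g"
    df.to_csv(path, sep="\t", na_rep="NA", float_format=fmt, index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], index_col=index_col)


def write_metrics(metrics: pd.DataFrame, path: str | Path,
                  full_precision: bool = False) -> None:
    """Write a per-generation metrics table (index = generation)."""
    write_table(metrics, path, full_precision=full_precision, index=True)


def read_metrics(path: str | Path) -> pd.DataFrame:
    return read_table(path, index_col="generation")


# --- population snapshots -----------------------------------------------------

def write_snapshot(pop: Population, path: str | Path) -> None:
    """Write a population as chromosome-per-row text (format above)."""
    with open(path, "w") as fh:
        fh.write(f"# generation={pop.generation}\n")
        fh.write("individual\tsex\thabitat\tchromosome\talleles\n")
        trait_lut = np.array([TRAIT_CHARS[0], TRAIT_CHARS[1]])
        site_lut = np.array([SITE_CHARS[c] for c in range(4)])
        for i in range(pop.n):
            sex = _SEX_CHARS[int(pop.sex[i])]
            hab = _HAB_CHARS[int(pop.habitat[i])]
            for c in range(2):
                chrom = pop.genomes[i, c]
                alleles = trait_lut[chrom[0]] + "".join(site_lut[chrom[1:]])
                fh.write(f"{i}\t{sex}\t{hab}\t{c}\t{alleles}\n")


def read_snapshot(path: str | Path) -> Population:
    """Read a snapshot written by :func:`write_snapshot`."""
    generation = 0
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("# generation="):
            generation = int(first.split("=", 1)[1])
            header = fh.readline()
        else:
            header = first
        if not header.strip().startswith("individual"):
            raise ValueError(f"{path} is not a population snapshot")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise ValueError(f"{path} contains no chromosomes")
    n = max(int(r[0]) for r in rows) + 1
    L = len(rows[0][4])
    genomes = np.zeros((n, 2, L), dtype=np.uint8)
    sex = np.zeros(n, dtype=np.uint8)
    habitat = np.zeros(n, dtype=np.uint8)
    for ind, sx, hab, chrom, alleles in rows:
        i, c = int(ind), int(chrom)
        sex[i] = 0 if sx == "F" else 1
        habitat[i] = 0 if hab == "H1" else 1
        genomes[i, c, 0] = _TRAIT_DECODE[alleles[0]]
        genomes[i, c, 1:] = [_SITE_DECODE[ch] for ch in alleles[1:]]
    return Population(genomes=genomes, sex=sex, habitat=habitat, generation=generation)


# --- test fixtures ------------------------------------------------------------

def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Emit tiny deterministic fixture files (population, config, metrics).

    Uses a miniature parameterization (K=10, L=10) run for a handful of
    generations; byte-identical for a given seed.
    """
    from .lifecycle import run_simulation

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = ModelParams(
        s=0.5, pf=0.6, K=10, L=10, mut_fraction=0.05, generations=5, seed=int(seed)
    )
    res = run_simulation(params, snapshot_generations=(params.generations,),
                         keep_final=True)
    paths = {
        "config": out / "fixture_config.yaml",
        "population": out / "fixture_population.tsv",
        "metrics": out / "fixture_metrics.tsv",
    }
    save_config(RunConfig(params=params), paths["config"])
    write_snapshot(res.final_population, paths["population"])
    write_metrics(res.metrics, paths["metrics"])
    return paths
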