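"""Readers and writers for the tab-separated text formats.

Three tables are defined:

- read counts: header ``site  ind  nA  nC  nG  nT``, one row per
  (site, individual); absent rows mean zero coverage;
- genotype likelihoods: header ``site  ind  AA AC AG AT CC CG CT GG GT TT``
  with natural-log values (a ``#loglik=natural`` comment line precedes
  the header on write);
- genotype calls: header ``site  ind  genotype`` with ``.`` for missing.

Plus a YAML run configuration that round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotype_calling import MISSING
from .likelihood_core import GENOTYPE_LABELS, ErrorMatrix, SiteReadData

COUNTS_COLUMNS = ["site", "ind", "nA", "nC", "nG", "nT"]
GL_COLUMNS = ["site", "ind", *GENOTYPE_LABELS]
CALLS_COLUMNS = ["site", "ind", "genotype"]
FLOAT_FORMAT = "%.12g"


class TableFormatError(ValueError):
    """Raised when an input table violates the format contract."""


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns) != columns:
        raise TableFormatError(
            f"{path}: expected header {columns}, found {list(df.columns)}"
        )
    return df


def _to_numeric(df: pd.DataFrame, cols: list[str], path: Path, integer: bool) -> pd.DataFrame:
    for col in cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            # +2 accounts for the header line and 1-based numbering
            line = int(bad.idxmax()) + 2
            raise TableFormatError(
                f"{path}: malformed value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {line}"
            )
        if integer and not np.all(converted.dropna() == converted.dropna().astype(int)):
            raise TableFormatError(f"{path}: column {col!r} must be integral")
        df[col] = converted.astype(int) if integer else converted.astype(float)
    return df


def read_counts_table(path: str | Path) -> dict[str, SiteReadData]:
    """Read a counts table into :class:`SiteReadData` keyed by site id.

    Individuals absent at a site (but present at others) get zero
    counts.  Duplicate (site, ind) rows and negative counts are errors.
    """
    path = Path(path)
    df = _read_tsv(path, COUNTS_COLUMNS)
    if df.empty:
        return {}
    df = _to_numeric(df, ["nA", "nC", "nG", "nT"], path, integer=True)
    if (df[["nA", "nC", "nG", "nT"]] < 0).any().any():
        raise TableFormatError(f"{path}: negative read count")
    if df.duplicated(subset=["site", "ind"]).any():
        dup = df[df.duplicated(subset=["site", "ind"])].iloc[0]
        raise TableFormatError(
            f"{path}: duplicate row for site {dup['site']!r}, individual {dup['ind']!r}"
        )
    individuals = list(dict.fromkeys(df["ind"]))
    ind_pos = {ind: k for k, ind in enumerate(individuals)}
    out: dict[str, SiteReadData] = {}
    for site_id, group in df.groupby("site", sort=False):
        counts = np.zeros((len(individuals), 4), dtype=np.int64)
        rows = [ind_pos[i] for i in group["ind"]]
        counts[rows] = group[["nA", "nC", "nG", "nT"]].to_numpy()
        out[str(site_id)] = SiteReadData(str(site_id), counts, list(individuals))
    return out


def write_counts_table(path: str | Path, sites: dict[str, SiteReadData]) -> None:
    records = []
    for site_id, site in sites.items():
        for ind, row in zip(site.individuals, site.counts):
            records.append((site_id, ind, *row.tolist()))
    df = pd.DataFrame(records, columns=COUNTS_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_gl_table(path: str | Path) -> dict[str, tuple[list[str], np.ndarray]]:
    """Read a genotype-likelihood table.

    Returns ``{site_id: (individual_ids, (N, 10) log-likelihood array)}``.
    Positive entries are rejected: likelihoods cannot exceed 1.
    """
    path = Path(path)
    df = _read_tsv(path, GL_COLUMNS)
    if df.empty:
        return {}
    df = _to_numeric(df, list(GENOTYPE_LABELS), path, integer=False)
    values = df[list(GENOTYPE_LABELS)].to_numpy()
    if np.any(values > 0):
        raise TableFormatError(
            f"{path}: positive log-likelihood entries (likelihoods must be <= 1)"
        )
    if df.duplicated(subset=["site", "ind"]).any():
        raise TableFormatError(f"{path}: duplicate (site, ind) row")
    out: dict[str, tuple[list[str], np.ndarray]] = {}
    for site_id, group in df.groupby("site", sort=False):
        out[str(site_id)] = (
            [str(i) for i in group["ind"]],
            group[list(GENOTYPE_LABELS)].to_numpy(dtype=float),
        )
    return out


def write_gl_table(
    path: str | Path, sites: dict[str, tuple[list[str], np.ndarray]]
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#loglik=natural\n")
        fh.write("\t".join(GL_COLUMNS) + "\n")
        for site_id, (inds, gl) in sites.items():
            for ind, row in zip(inds, np.asarray(gl)):
                vals = "\t".join(FLOAT_FORMAT % v for v in row)
                fh.write(f"{site_id}\t{ind}\t{vals}\n")


def read_calls_table(path: str | Path) -> pd.DataFrame:
    """Read a calls table; missing genotypes (``.``) become -1."""
    path = Path(path)
    df = _read_tsv(path, CALLS_COLUMNS)
    geno = df["genotype"].replace(".", str(MISSING))
    df = df.assign(genotype=pd.to_numeric(geno, errors="coerce"))
    if df["genotype"].isna().any() or not df["genotype"].isin([-1, 0, 1, 2]).all():
        raise TableFormatError(f"{path}: genotype codes must be 0, 1, 2 or '.'")
    df["genotype"] = df["genotype"].astype(int)
    return df


def write_calls_table(path: str | Path, df: pd.DataFrame) -> None:
    out = df.copy()
    out["genotype"] = out["genotype"].astype(object)
    out.loc[out["genotype"] == MISSING, "genotype"] = "."
    out.to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Run configuration; round-trips through YAML losslessly."""

    error: ErrorMatrix = field(default_factory=ErrorMatrix.uniform)
    optimizer: str = "em"
    filter_f: float = 0.0
    tolerance: float = 1e-3
    seed: int | None = None
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "error": self.error.to_dict(),
            "optimizer": self.optimizer,
            "filter_f": self.filter_f,
            "tolerance": self.tolerance,
            "seed": self.seed,
            "log_level": self.log_level,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            error=ErrorMatrix.from_dict(payload["error"]),
            optimizer=payload["optimizer"],
            filter_f=float(payload["filter_f"]),
            tolerance=float(payload["tolerance"]),
            seed=payload["seed"],
            log_level=payload["log_level"],
        )


def counts_to_array(sites: dict[str, SiteReadData]) -> tuple[list[str], np.ndarray]:
    """Stack a counts collection into (site_ids, (S, N, 4) array).

    Requires every site to carry the same individual roster, which
    :func:`read_counts_table` guarantees.
    """
    ids = list(sites)
    if not ids:
        return [], np.zeros((0, 0, 4), dtype=np.int64)
    return ids, np.stack([sites[s].counts for s in ids])
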