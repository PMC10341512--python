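"""Feature-table container and delimited-text input/output.

The on-disk convention: first column sample id, second column group label,
remaining columns metabolite peak areas, header row carries metabolite
names. Comma- or tab-delimited is auto-detected from the file extension
(.csv → comma, anything else → tab); decimal point only. Empty cells, "NA"
and "NaN" are missing; zero intensities are treated as missing downstream
(LC–MS non-detects).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("metamark")

__all__ = ["FeatureTable", "read_feature_table", "write_table", "read_table"]

NA_TOKENS = ("", "NA", "NaN", "nan")

#: valid normalization states, in pipeline order
SCALE_STATES = ("raw", "tss", "tss_log10")


@dataclass
class FeatureTable:
    """Sample × metabolite intensity matrix with group labels.

    ``intensities`` is a pandas DataFrame (rows = samples, columns =
    metabolites); missing values are NaN, never zero-filled.
    ``scale_state`` tracks the normalization chain: ``raw`` → ``tss``
    (rows sum to one) → ``tss_log10``.
    """

    intensities: pd.DataFrame
    group_labels: pd.Series
    scale_state: str = "raw"
    annotations: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.intensities = self.intensities.astype(float)
        self.group_labels = pd.Series(self.group_labels,
                                      index=self.intensities.index)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.scale_state not in SCALE_STATES:
            raise ValueError(f"unknown scale_state {self.scale_state!r}")
        idx = self.intensities.index
        cols = self.intensities.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dups}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValueError(f"duplicate metabolite ids: {dups}")
        if len(self.group_labels) != len(idx):
            raise ValueError("one group label required per sample")
        vals = self.intensities.to_numpy()
        if self.scale_state in ("raw", "tss") and np.nanmin(vals, initial=0) < 0:
            raise ValueError(f"negative intensities invalid in state "
                             f"{self.scale_state!r}")
        if self.scale_state == "tss":
            sums = np.nansum(vals, axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("tss rows must each sum to 1 within 1e-9")
        if self.annotations is not None and not self.annotations.index.equals(cols):
            raise ValueError("annotations must be indexed by metabolite id")

    # -- conveniences -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.intensities.shape[1]

    def groups(self) -> list[str]:
        return list(pd.unique(self.group_labels))

    def require_groups(self, *names: str) -> None:
        missing = [g for g in names if g not in set(self.group_labels)]
        if missing:
            raise KeyError(f"group(s) not present in table: {missing}; "
                           f"available: {sorted(set(self.group_labels))}")

    def subset_groups(self, *names: str) -> "FeatureTable":
        """Restrict to the samples of the named groups, order preserved."""
        self.require_groups(*names)
        mask = self.group_labels.isin(names).to_numpy()
        return self.replace(intensities=self.intensities.loc[mask])

    def replace(self, **changes) -> "FeatureTable":
        new = dataclasses.replace(self, **changes)
        if "intensities" in changes and "group_labels" not in changes:
            new.group_labels = self.group_labels.loc[new.intensities.index]
        return new


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_feature_table(path: str | Path, *, transposed: bool = False) -> FeatureTable:
    """Read a delimited peak-area table into a validated :class:`FeatureTable`.

    Missing cells (empty, "NA", "NaN") become NaN, never zero. With
    ``transposed=True`` the file holds metabolites as rows and samples as
    columns after the two label columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, comment="#",
                      keep_default_na=False)
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: need sample id, group label and at least "
                         "one metabolite column")
    if transposed:
        raw = _untranspose(raw)
    sample_ids = raw.iloc[:, 0].astype(str)
    if sample_ids.duplicated().any():
        dups = sorted(set(sample_ids[sample_ids.duplicated()]))
        raise ValueError(f"{path}: duplicate sample ids: {dups}")
    groups = pd.Series(raw.iloc[:, 1].astype(str).to_numpy(),
                       index=sample_ids.to_numpy())
    body = raw.iloc[:, 2:]
    values = np.full(body.shape, np.nan)
    for j, col in enumerate(body.columns):
        for i, cell in enumerate(body[col].to_numpy()):
            cell = cell.strip()
            if cell in NA_TOKENS:
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric intensity {cell!r} at row "
                    f"{sample_ids.iloc[i]!r}, column {col!r}") from None
    intens = pd.DataFrame(values, index=sample_ids.to_numpy(),
                          columns=[str(c) for c in body.columns])
    return FeatureTable(intens, groups, scale_state="raw")


def _untranspose(raw: pd.DataFrame) -> pd.DataFrame:
    """Metabolite-per-row layout → sample-per-row layout.

    Expected transposed layout: first column metabolite id, remaining columns
    one per sample; a mandatory first data row named 'group' holds labels.
    """
    raw = raw.set_index(raw.columns[0])
    if "group" not in raw.index:
        raise ValueError("transposed layout requires a 'group' row")
    groups = raw.loc["group"]
    body = raw.drop(index="group").T
    out = body.reset_index().rename(columns={"index": "sample_id"})
    out.insert(1, "group", groups.to_numpy())
    return out


def write_table(result, path: str | Path, *, provenance: str | None = None) -> Path:
    """Write a tabular result as delimited text with a commented header line.

    Floats are written with 17 significant digits so a read-back reproduces
    them to machine precision. Empty results are rejected rather than
    producing a misleading empty file.
    """
    if isinstance(result, FeatureTable):
        df = result.intensities.copy()
        df.insert(0, "group", result.group_labels.to_numpy())
        df.index.name = "sample_id"
        df = df.reset_index()
        if provenance is None:
            provenance = f"feature table, scale_state={result.scale_state}"
    elif isinstance(result, pd.Series):
        df = result.rename_axis("id").reset_index()
    else:
        df = pd.DataFrame(result)
        if df.index.name is not None or not isinstance(df.index, pd.RangeIndex):
            df = df.rename_axis(df.index.name or "id").reset_index()
    if df.empty:
        raise ValueError(f"refusing to write empty result to {path}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# metamark {provenance or 'result table'}\n")
        df.to_csv(fh, sep=_sep_for(path), index=False, float_format="%.17g")
    logger.info("wrote %s (%d rows)", path, len(df))
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep=_sep_for(Path(path)), comment="#")
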