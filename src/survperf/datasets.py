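"""Survival cohort containers and tab-separated file I/O.

A cohort couples right-censored survival outcomes (observed time ``T_i`` and
event indicator ``delta_i``) with two blocks of covariates: a small set of
clinical variables and a large gene-expression matrix.  The on-disk format is
two TSV files:

* clinical: header ``id  time  event  <covariate...>``, one row per sample;
* expression: header ``gene_id  <sample id...>``, one row per gene.

Categorical clinical variables must be numerically encoded by the user before
loading; the reader rejects non-numeric columns by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalSample",
    "SurvivalDataset",
    "read_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SurvivalSample:
    """One subject: outcome plus clinical and expression covariates."""

    id: str
    time: float
    event: int
    clinical: Mapping[str, float]
    expression: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"sample {self.id!r}: time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"sample {self.id!r}: event must be 0 or 1, got {self.event}")


@dataclass
class SurvivalDataset:
    """A cohort of subjects with aligned outcome, clinical and expression blocks.

    Internally column-major numpy arrays; ``samples`` offers a per-subject view.

    Parameters
    ----------
    ids : sample identifiers, unique.
    time : observed times, strictly positive (study units, e.g. years).
    event : 1 = event observed, 0 = right-censored.
    clinical : (n_samples, n_clinical) array.
    clinical_names : ordered clinical covariate names.
    expression : (n_samples, n_genes) array.
    gene_names : ordered gene names.
    """

    ids: list[str]
    time: np.ndarray
    event: np.ndarray
    clinical: np.ndarray
    clinical_names: list[str]
    expression: np.ndarray
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.clinical = np.atleast_2d(np.asarray(self.clinical, dtype=float))
        self.expression = np.atleast_2d(np.asarray(self.expression, dtype=float))
        n = len(self.ids)
        if self.clinical.size == 0:
            self.clinical = self.clinical.reshape(n, 0)
        if self.expression.size == 0:
            self.expression = self.expression.reshape(n, 0)
        if len(set(self.ids)) != n:
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate sample id {dup!r}")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match number of samples")
        if np.any(self.time <= 0):
            bad = self.ids[int(np.argmax(self.time <= 0))]
            raise ValueError(f"sample {bad!r}: time must be > 0")
        if not np.isin(self.event, (0, 1)).all():
            bad = self.ids[int(np.argmax(~np.isin(self.event, (0, 1))))]
            raise ValueError(f"sample {bad!r}: event must be 0 or 1")
        self.event = self.event.astype(int)
        if self.clinical.shape != (n, len(self.clinical_names)):
            raise ValueError("clinical block shape mismatch")
        if self.expression.shape != (n, len(self.gene_names)):
            raise ValueError("expression block shape mismatch")

    # -- basic views ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def samples(self) -> Iterator[SurvivalSample]:
        for i, sid in enumerate(self.ids):
            yield SurvivalSample(
                id=sid,
                time=float(self.time[i]),
                event=int(self.event[i]),
                clinical=dict(zip(self.clinical_names, self.clinical[i])),
                expression=dict(zip(self.gene_names, self.expression[i])),
            )

    def gene_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in names if g not in lookup]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        return np.array([lookup[g] for g in names], dtype=int)

    def subset(self, index: Sequence[int]) -> "SurvivalDataset":
        """New dataset holding the given subjects (by positional index)."""
        index = np.asarray(index, dtype=int)
        return SurvivalDataset(
            ids=[self.ids[i] for i in index],
            time=self.time[index],
            event=self.event[index],
            clinical=self.clinical[index],
            clinical_names=list(self.clinical_names),
            expression=self.expression[index],
            gene_names=list(self.gene_names),
        )

    def with_outcomes(self, time: np.ndarray, event: np.ndarray) -> "SurvivalDataset":
        """Copy with replaced (time, event); covariate blocks are shared."""
        out = SurvivalDataset(
            ids=list(self.ids),
            time=np.asarray(time, dtype=float).copy(),
            event=np.asarray(event).copy(),
            clinical=self.clinical,
            clinical_names=list(self.clinical_names),
            expression=self.expression,
            gene_names=list(self.gene_names),
        )
        return out


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")


def read_dataset(clinical_path: str | Path, expression_path: str | Path | None = None) -> SurvivalDataset:
    """Load a cohort from a clinical TSV and an optional expression TSV.

    Samples present in the clinical table but absent from the expression
    table (or vice versa) are an error: the two blocks must describe exactly
    the same subjects.
    """
    clin = _read_tsv(clinical_path)
    required = ["id", "time", "event"]
    if list(clin.columns[:3]) != required:
        raise ValueError(f"clinical file must start with columns {required}, got {list(clin.columns[:3])}")
    ids = clin["id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dup = clin["id"][clin["id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in {clinical_path}")
    covariate_names = list(clin.columns[3:])
    for col in ["time", "event"] + covariate_names:
        if not pd.api.types.is_numeric_dtype(clin[col]):
            raise ValueError(f"column {col!r} is not numeric; encode categoricals before loading")

    if expression_path is None:
        expr = np.empty((len(ids), 0))
        gene_names: list[str] = []
    else:
        mat = _read_tsv(expression_path)
        gene_names = mat.iloc[:, 0].astype(str).tolist()
        expr_ids = list(mat.columns[1:])
        orphan = sorted(set(expr_ids) - set(ids))
        if orphan:
            raise ValueError(f"expression file sample(s) missing from clinical table: {orphan}")
        missing = sorted(set(ids) - set(expr_ids))
        if missing:
            raise ValueError(f"clinical sample(s) missing from expression file: {missing}")
        expr = mat[ids].to_numpy(dtype=float).T  # genes x samples -> samples x genes

    return SurvivalDataset(
        ids=ids,
        time=clin["time"].to_numpy(dtype=float),
        event=clin["event"].to_numpy(),
        clinical=clin[covariate_names].to_numpy(dtype=float) if covariate_names else np.empty((len(ids), 0)),
        clinical_names=covariate_names,
        expression=expr,
        gene_names=gene_names,
    )


def write_dataset(ds: SurvivalDataset, clinical_path: str | Path, expression_path: str | Path | None = None,
                  header_lines: Sequence[str] = ()) -> None:
    """Write the cohort back out in the canonical two-file TSV layout."""
    clin = pd.DataFrame({"id": ds.ids, "time": ds.time, "event": ds.event})
    for j, name in enumerate(ds.clinical_names):
        clin[name] = ds.clinical[:, j]
    with open(clinical_path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        clin.to_csv(fh, sep="\t", index=False)
    if expression_path is not None:
        mat = pd.DataFrame(ds.expression.T, index=pd.Index(ds.gene_names, name="gene_id"), columns=ds.ids)
        with open(expression_path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            mat.to_csv(fh, sep="\t")
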