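"""Core dataset container, log/standardize transforms, and evaluation masks.

A bottom-up proteomics experiment is represented as a wide peptide table:
``n`` peptides (rows, each mapping to one or more protein accessions)
quantified across ``s`` samples (columns).  Missing intensities are IEEE
NaN internally; common on-disk markers (0, "NA", blank) are mapped at load
time via :class:`TableDialect`.

Two ground-truth mechanisms for benchmarking imputers are provided:

* ``masked`` — hide a fraction of observed values uniformly at random and
  use the hidden values as truth.
* ``dda_dia`` — a DDA run paired with a DIA run of the same samples; DDA
  entries that are missing but have a DIA measurement form the test set,
  with the (mean-matched) DIA value as truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TableDialect",
    "PeptideDataset",
    "TransformState",
    "MaskPlan",
    "load_peptide_table",
    "write_peptide_table",
    "read_fasta_sequences",
    "read_sample_groups",
    "log_standardize",
    "inverse_transform",
    "make_masked_split",
    "make_dda_dia_split",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass(frozen=True)
class TableDialect:
    """Parsing conventions for wide peptide tables.

    MaxQuant ``peptides.txt``-style files are covered by the defaults:
    tab separation, ";"-separated protein accessions, zeros treated as
    missing (MaxQuant writes 0 for unquantified peptides).
    """

    sep: str = "\t"
    peptide_col: str = "peptide_id"
    protein_col: str = "protein_groups"
    protein_sep: str = ";"
    missing_tokens: tuple = ("", "NA", "NaN", "nan")
    zero_as_missing: bool = True


@dataclass
class PeptideDataset:
    """Wide peptide abundance matrix with peptide-to-protein mapping.

    ``abundance`` holds raw-scale (strictly positive) intensities with NaN
    for missing values.  ``protein_groups[i]`` is the non-empty set of
    protein accessions peptide ``i`` maps to; shared (non-unique) peptides
    carry more than one accession.
    """

    abundance: np.ndarray
    peptide_ids: list
    protein_groups: list
    sample_ids: list
    sample_groups: dict | None = None
    sequences: dict | None = None  # peptide_id -> amino-acid sequence

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.ndim != 2:
            raise DataError("abundance must be a 2-D matrix")
        n, s = self.abundance.shape
        if n < 1 or s < 2:
            raise DataError(f"need >= 1 peptide and >= 2 samples, got {n} x {s}")
        if len(self.peptide_ids) != n or len(self.sample_ids) != s:
            raise DataError("id lists inconsistent with matrix shape")
        if len(set(self.peptide_ids)) != n:
            raise DataError("duplicate peptide ids")
        if len(set(self.sample_ids)) != s:
            raise DataError("duplicate sample ids")
        if len(self.protein_groups) != n:
            raise DataError("protein_groups length mismatch")
        self.protein_groups = [frozenset(g) for g in self.protein_groups]
        if any(len(g) == 0 for g in self.protein_groups):
            raise DataError("every peptide must map to >= 1 protein")
        obs = self.abundance[np.isfinite(self.abundance)]
        if obs.size and np.any(obs <= 0):
            raise DataError("non-missing abundances must be strictly positive (raw scale)")

    @property
    def n_peptides(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    @property
    def observed_mask(self) -> np.ndarray:
        return np.isfinite(self.abundance)

    def missing_fraction(self) -> float:
        return float(np.mean(~self.observed_mask))

    def peptide_missing_fractions(self) -> np.ndarray:
        """Per-peptide fraction of missing values across samples."""
        return np.mean(~self.observed_mask, axis=1)


@dataclass(frozen=True)
class TransformState:
    """Natural-log mean/sd used for standardization (missing ignored).

    For the default global scope both are scalars; per-sample scope
    stores one value per column (shape (1, s)), per-peptide scope one per
    row (shape (n, 1)).  They broadcast against the matrix either way.
    """

    global_mean: float | np.ndarray
    global_sd: float | np.ndarray
    scope: str = "global"


@dataclass
class MaskPlan:
    """Disjoint test/validation positions with ground-truth values.

    Positions are (row, column) pairs into the dataset matrix; truth values
    are on the standardized-log scale of the source dataset.
    """

    test_idx: np.ndarray  # (m, 2) int
    val_idx: np.ndarray  # (k, 2) int
    truth: dict  # (i, j) -> standardized-log truth
    mechanism: str  # "masked" | "dda_dia"

    def __post_init__(self):
        self.test_idx = np.asarray(self.test_idx, dtype=int).reshape(-1, 2)
        self.val_idx = np.asarray(self.val_idx, dtype=int).reshape(-1, 2)
        test = {tuple(p) for p in self.test_idx}
        val = {tuple(p) for p in self.val_idx}
        if test & val:
            raise DataError("test and validation positions overlap")
        for p in test | val:
            if p not in self.truth:
                raise DataError(f"position {p} lacks a ground-truth value")
        if self.mechanism not in ("masked", "dda_dia"):
            raise DataError(f"unknown mechanism {self.mechanism!r}")

    def truth_at(self, idx: np.ndarray) -> np.ndarray:
        return np.array([self.truth[tuple(p)] for p in np.asarray(idx).reshape(-1, 2)])

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        """Return a copy of `matrix` with test and validation entries set to NaN."""
        out = matrix.copy()
        for idx in (self.test_idx, self.val_idx):
            if len(idx):
                out[idx[:, 0], idx[:, 1]] = np.nan
        return out


# ---------------------------------------------------------------------------
# I/O


def load_peptide_table(path, dialect: TableDialect = TableDialect()) -> PeptideDataset:
    """Read a wide peptide table (TSV/CSV) into a :class:`PeptideDataset`."""
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    for col in (dialect.peptide_col, dialect.protein_col):
        if col not in df.columns:
            raise DataError(f"missing required column {col!r} in {path}")
    sample_cols = [c for c in df.columns if c not in (dialect.peptide_col, dialect.protein_col)]
    if len(sample_cols) < 2:
        raise DataError(f"need >= 2 sample columns, found {len(sample_cols)}")
    peptide_ids = df[dialect.peptide_col].tolist()
    if len(set(peptide_ids)) != len(peptide_ids):
        dupes = df[dialect.peptide_col][df[dialect.peptide_col].duplicated()].unique()
        raise DataError(f"duplicate peptide ids: {list(dupes)[:5]}")
    protein_groups = [
        frozenset(t.strip() for t in cell.split(dialect.protein_sep) if t.strip())
        for cell in df[dialect.protein_col]
    ]
    values = np.full((len(df), len(sample_cols)), np.nan)
    for j, col in enumerate(sample_cols):
        raw = df[col].str.strip()
        is_missing = raw.isin(dialect.missing_tokens)
        parsed = pd.to_numeric(raw.mask(is_missing), errors="raise").to_numpy(dtype=float)
        if dialect.zero_as_missing:
            parsed[parsed == 0] = np.nan
        values[:, j] = parsed
    return PeptideDataset(values, peptide_ids, protein_groups, sample_cols)


def write_peptide_table(ds: PeptideDataset, path, dialect: TableDialect = TableDialect()):
    """Write a dataset back to the wide-table format the loader reads."""
    df = pd.DataFrame(ds.abundance, columns=ds.sample_ids)
    df.insert(0, dialect.protein_col, [dialect.protein_sep.join(sorted(g)) for g in ds.protein_groups])
    df.insert(0, dialect.peptide_col, ds.peptide_ids)
    df.to_csv(path, sep=dialect.sep, index=False, na_rep="NA")


def read_fasta_sequences(path) -> dict:
    """Read peptide sequences from FASTA; ids must match the peptide-id column."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta_sequences(seqs: dict, path):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_sample_groups(path) -> dict:
    """Two-column TSV (sample_id, group) -> dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError("sample-group metadata needs two columns (sample_id, group)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# Transforms


def log_standardize(ds_or_matrix, scope: str = "global") -> tuple[np.ndarray, TransformState]:
    """Natural log + zero-mean/unit-variance standardization.

    Missing values are ignored when computing the moments and preserved
    as NaN in the output.  The sample standard deviation (ddof=1) is
    used.  ``scope`` selects one global mean/sd (default, matching the
    matrix-level formulation), or per-sample / per-peptide moments.
    """
    A = ds_or_matrix.abundance if isinstance(ds_or_matrix, PeptideDataset) else np.asarray(ds_or_matrix, dtype=float)
    obs = np.isfinite(A)
    if not obs.any():
        raise DataError("all values are missing")
    vals = A[obs]
    if np.any(vals <= 0):
        raise DataError("non-positive abundance on raw scale")
    logged = np.where(obs, np.log(np.where(obs, A, 1.0)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if scope == "global":
            mean = float(np.mean(logged[obs]))
            sd = float(np.std(logged[obs], ddof=1)) if obs.sum() > 1 else 0.0
        elif scope == "per_sample":
            mean = np.nanmean(logged, axis=0, keepdims=True)
            sd = np.nanstd(logged, axis=0, ddof=1, keepdims=True)
        elif scope == "per_peptide":
            mean = np.nanmean(logged, axis=1, keepdims=True)
            sd = np.nanstd(logged, axis=1, ddof=1, keepdims=True)
        else:
            raise DataError(f"unknown standardization scope {scope!r}")
    if not np.all(np.asarray(sd) > 0):
        raise DataError("zero variance: cannot standardize")
    return (logged - mean) / sd, TransformState(mean, sd, scope)


def inverse_transform(std_matrix: np.ndarray, state: TransformState) -> np.ndarray:
    """Map standardized-log values back to the raw measurement scale."""
    return np.exp(np.asarray(std_matrix, dtype=float) * state.global_sd + state.global_mean)


# ---------------------------------------------------------------------------
# Mask plans


def _sample_positions(rng: np.random.Generator, positions: np.ndarray, count: int) -> np.ndarray:
    pick = rng.choice(len(positions), size=count, replace=False)
    return positions[np.sort(pick)]


def _subset_size(frac: float, count: int, what: str) -> int:
    if not 0 < frac < 1:
        raise DataError(f"{what} fraction must lie in (0, 1), got {frac}")
    size = max(1, int(np.floor(frac * count)))
    if size > count:
        raise DataError(f"cannot draw {size} {what} positions from {count}")
    return size


def make_masked_split(
    ds: PeptideDataset,
    test_frac: float = 0.10,
    val_frac: float = 0.10,
    seed: int = 0,
) -> MaskPlan:
    """Uniformly-at-random masking ground truth.

    The test set is ``floor(test_frac * #observed)`` positions (minimum 1)
    drawn uniformly from observed entries; the validation set is drawn the
    same way from the entries remaining after the test draw.
    """
    std, _ = log_standardize(ds)
    observed = np.argwhere(np.isfinite(std))
    n_obs = len(observed)
    if n_obs < 2:
        raise DataError("not enough observed values to split")
    rng = np.random.default_rng(seed)
    n_test = _subset_size(test_frac, n_obs, "test")
    test_idx = _sample_positions(rng, observed, n_test)
    test_set = {tuple(p) for p in test_idx}
    remaining = np.array([p for p in observed if tuple(p) not in test_set])
    if len(remaining) == 0:
        raise DataError("no observed values left for validation")
    n_val = _subset_size(val_frac, len(remaining), "validation")
    val_idx = _sample_positions(rng, remaining, n_val)
    truth = {tuple(p): float(std[p[0], p[1]]) for p in np.vstack([test_idx, val_idx])}
    return MaskPlan(test_idx, val_idx, truth, "masked")


def make_dda_dia_split(
    dda: PeptideDataset,
    dia: PeptideDataset,
    val_frac: float = 0.10,
    seed: int = 0,
    scale: str = "log",
) -> tuple[np.ndarray, MaskPlan]:
    """DDA/DIA pairing ground truth.

    The two datasets are intersected on peptide and sample ids (dropped
    rows/columns trigger a warning).  DIA values are shifted on the log
    scale so their observed mean matches the DDA observed mean (``scale=
    "raw"`` instead rescales multiplicatively on the raw scale).  Test
    positions are entries missing in DDA but observed in DIA; truth is the
    mean-matched DIA value expressed on DDA's standardized-log scale.
    Validation positions are drawn uniformly from observed DDA entries.

    Returns the mean-matched DIA log-scale matrix (aligned to the DDA
    intersection) and the mask plan, whose indices refer to the row/column
    order of `dda` restricted to the shared peptides and samples.
    """
    pep_common = [p for p in dda.peptide_ids if p in set(dia.peptide_ids)]
    smp_common = [s for s in dda.sample_ids if s in set(dia.sample_ids)]
    if not pep_common or not smp_common:
        raise DataError("DDA and DIA datasets share no peptides/samples")
    dropped = (len(dda.peptide_ids) - len(pep_common)) + (len(dda.sample_ids) - len(smp_common))
    if dropped:
        warnings.warn(f"DDA/DIA intersection dropped {dropped} non-shared rows/columns")

    def _align(ds: PeptideDataset) -> np.ndarray:
        ri = [ds.peptide_ids.index(p) for p in pep_common]
        ci = [ds.sample_ids.index(s) for s in smp_common]
        return ds.abundance[np.ix_(ri, ci)]

    A_dda = _align(dda)
    A_dia = _align(dia)
    obs_dda = np.isfinite(A_dda)
    obs_dia = np.isfinite(A_dia)
    if scale == "log":
        log_dda = np.where(obs_dda, np.log(np.where(obs_dda, A_dda, 1.0)), np.nan)
        log_dia = np.where(obs_dia, np.log(np.where(obs_dia, A_dia, 1.0)), np.nan)
        shift = np.nanmean(log_dda) - np.nanmean(log_dia)
        dia_scaled_log = log_dia + shift
    elif scale == "raw":
        factor = np.nanmean(A_dda) / np.nanmean(A_dia)
        dia_scaled_log = np.where(obs_dia, np.log(np.where(obs_dia, A_dia, 1.0) * factor), np.nan)
    else:
        raise DataError(f"unknown scale {scale!r}")

    sub = PeptideDataset(
        A_dda,
        pep_common,
        [dda.protein_groups[dda.peptide_ids.index(p)] for p in pep_common],
        smp_common,
    )
    std_dda, state = log_standardize(sub)
    test_idx = np.argwhere(~obs_dda & obs_dia)
    if len(test_idx) == 0:
        raise DataError("no position is missing in DDA but observed in DIA")
    truth = {
        tuple(p): float((dia_scaled_log[p[0], p[1]] - state.global_mean) / state.global_sd)
        for p in test_idx
    }
    rng = np.random.default_rng(seed)
    observed = np.argwhere(obs_dda)
    n_val = _subset_size(val_frac, len(observed), "validation")
    val_idx = _sample_positions(rng, observed, n_val)
    for p in val_idx:
        truth[tuple(p)] = float(std_dda[p[0], p[1]])
    return dia_scaled_log, MaskPlan(test_idx, val_idx, truth, "dda_dia")
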