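"""Reading, filtering and binning of MSAP fragment peak tables.

MSAP genotyping produces, for every sample and each of the two isoschizomer
digests (EcoRI/HpaII and EcoRI/MspI), a table of electrophoresis peaks:
fragment size in base pairs and peak height in relative fluorescence units
(RFU), as exported by capillary-sequencer genotyping software. This module
turns those tables into per-enzyme binary presence/absence matrices:

1. :func:`read_peak_table` parses a delimited peak table using a
   column-mapping dialect;
2. :func:`filter_peaks` removes background noise (low-RFU peaks) and peaks
   outside the scorable size window;
3. :func:`bin_fragments` assigns peaks to fixed-width size bins anchored at
   0 bp and scores each sample 0/1 per bin;
4. :func:`check_control_consistency` compares a control sample's binary
   profile between electrophoresis runs.

Peak *detection* (electropherogram signal processing) is out of scope: we
consume the genotyping software's output tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HPAII = "HpaII"
MSPI = "MspI"
ENZYMES = (HPAII, MSPI)

#: Default scoring thresholds: peaks must exceed 100 RFU (strictly) and lie
#: inside the closed size window [150, 500] bp.
DEFAULT_MIN_RFU = 100.0
DEFAULT_SIZE_MIN = 150.0
DEFAULT_SIZE_MAX = 500.0
DEFAULT_BIN_WIDTH = 0.5

_ENZYME_SYNONYMS = {
    "hpaii": HPAII,
    "hpa": HPAII,
    "h": HPAII,
    "mspi": MSPI,
    "msp": MSPI,
    "m": MSPI,
}


def normalize_enzyme(value: str) -> str:
    """Map an enzyme label (case-insensitive, common abbreviations) to
    'HpaII' or 'MspI'; raise ``ValueError`` for anything else."""
    key = str(value).strip().lower()
    if key not in _ENZYME_SYNONYMS:
        raise ValueError(f"unknown enzyme label: {value!r} (expected HpaII or MspI)")
    return _ENZYME_SYNONYMS[key]


@dataclass(frozen=True)
class PeakRecord:
    """One detected fragment peak.

    Attributes
    ----------
    sample_id : str
    enzyme : str
        'HpaII' or 'MspI' (the methylation-sensitive digest the profile
        came from; the EcoRI partner is implicit).
    run_id : str
        Electrophoresis run identifier, used for control-sample checks.
    size : float
        Fragment length in bp (fractional sizes from the internal size
        standard are normal).
    height : float
        Peak height in RFU, nonnegative.
    """

    sample_id: str
    enzyme: str
    run_id: str
    size: float
    height: float

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise ValueError(f"enzyme must be one of {ENZYMES}, got {self.enzyme!r}")
        if not self.size > 0:
            raise ValueError(f"size must be > 0 bp, got {self.size}")
        if self.height < 0:
            raise ValueError(f"height must be >= 0 RFU, got {self.height}")


@dataclass(frozen=True)
class PeakTableDialect:
    """Column mapping for a delimited peak table.

    Field values are the column names in the file; ``run`` may be ``None``
    when the table has no run column (all rows get ``default_run``).
    """

    sample: str = "sample"
    enzyme: str = "enzyme"
    run: str | None = "run"
    size: str = "size_bp"
    height: str = "height_rfu"
    delimiter: str = "\t"
    default_run: str = "run1"


@dataclass
class BinnedMatrix:
    """Samples x size-bins binary presence matrix for one enzyme.

    Bins are half-open intervals ``[k*w, (k+1)*w)`` anchored at 0 bp;
    ``bin_indices`` holds the sorted integers ``k`` of the occupied bins.
    """

    sample_ids: list[str]
    bin_indices: np.ndarray
    bin_width: float
    presence: np.ndarray
    enzyme: str

    def __post_init__(self) -> None:
        self.bin_indices = np.asarray(self.bin_indices, dtype=np.int64)
        self.presence = np.asarray(self.presence, dtype=np.uint8)
        if self.presence.shape != (len(self.sample_ids), len(self.bin_indices)):
            raise ValueError("presence shape does not match sample/bin ids")
        if not np.isin(self.presence, [0, 1]).all():
            raise ValueError("presence entries must be 0/1")
        if np.any(np.diff(self.bin_indices) <= 0):
            raise ValueError("bin indices must be strictly increasing")
        if self.enzyme not in ENZYMES:
            raise ValueError(f"enzyme must be one of {ENZYMES}")

    @property
    def bin_edges(self) -> np.ndarray:
        """(n_bins, 2) array of [left, right) bp breakpoints."""
        left = self.bin_indices * self.bin_width
        return np.column_stack([left, left + self.bin_width])

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_indices + 0.5) * self.bin_width

    def to_frame(self) -> pd.DataFrame:
        """Samples in rows, bin midpoints (bp) as column labels."""
        cols = [f"{m:g}" for m in self.bin_midpoints]
        return pd.DataFrame(self.presence, index=self.sample_ids, columns=cols)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, path: str | Path, enzyme: str, bin_width: float = DEFAULT_BIN_WIDTH) -> "BinnedMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        mids = np.array([float(c) for c in df.columns])
        indices = np.floor(mids / bin_width).astype(np.int64)
        order = np.argsort(indices)
        return cls(
            sample_ids=[str(s) for s in df.index],
            bin_indices=indices[order],
            bin_width=bin_width,
            presence=df.to_numpy()[:, order],
            enzyme=normalize_enzyme(enzyme),
        )


def read_peak_table(
    path: str | Path,
    dialect: PeakTableDialect = PeakTableDialect(),
) -> list[PeakRecord]:
    """Parse a delimited peak table into :class:`PeakRecord` objects.

    Rows whose size/height cannot be parsed as numbers (or whose enzyme
    label is unknown) are not silently dropped: each rejection is reported
    via ``warnings.warn`` with the offending row number.

    Raises
    ------
    FileNotFoundError
        Missing file.
    KeyError
        A mapped column is absent from the header.
    ValueError
        The file contains no data rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    if df.empty:
        raise ValueError(f"empty peak table: {path}")
    needed = [dialect.sample, dialect.enzyme, dialect.size, dialect.height]
    if dialect.run is not None:
        needed.append(dialect.run)
    for col in needed:
        if col not in df.columns:
            raise KeyError(f"mapped column {col!r} not found in {path} (columns: {list(df.columns)})")

    records: list[PeakRecord] = []
    for pos in range(len(df)):
        row = df.iloc[pos]
        try:
            rec = PeakRecord(
                sample_id=str(row[dialect.sample]),
                enzyme=normalize_enzyme(row[dialect.enzyme]),
                run_id=str(row[dialect.run]) if dialect.run else dialect.default_run,
                size=float(row[dialect.size]),
                height=float(row[dialect.height]),
            )
        except (TypeError, ValueError) as exc:
            # +2: one for the header line, one for 1-based numbering
            warnings.warn(f"{path}:{pos + 2}: rejected peak row ({exc})", stacklevel=2)
            continue
        records.append(rec)
    return records


def write_peak_table(
    records: Iterable[PeakRecord],
    path: str | Path,
    dialect: PeakTableDialect = PeakTableDialect(),
) -> None:
    """Write records as a delimited table readable by :func:`read_peak_table`."""
    rows = [
        {
            dialect.sample: r.sample_id,
            dialect.enzyme: r.enzyme,
            (dialect.run or "run"): r.run_id,
            dialect.size: r.size,
            dialect.height: r.height,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=dialect.delimiter, index=False)


def filter_peaks(
    records: Sequence[PeakRecord],
    min_rfu: float = DEFAULT_MIN_RFU,
    size_min: float = DEFAULT_SIZE_MIN,
    size_max: float = DEFAULT_SIZE_MAX,
) -> list[PeakRecord]:
    """Keep peaks with height strictly above ``min_rfu`` and size inside the
    closed window ``[size_min, size_max]``; order is preserved.

    The RFU cut is strict (a peak at exactly the threshold is background by
    definition of the threshold); the size window endpoints are inclusive.
    """
    if min_rfu <= 0 or size_min <= 0 or size_max <= 0:
        raise ValueError("thresholds must be positive")
    if not size_min < size_max:
        raise ValueError("size_min must be < size_max")
    return [
        r for r in records
        if r.height > min_rfu and size_min <= r.size <= size_max
    ]


def bin_fragments(
    records: Sequence[PeakRecord],
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> BinnedMatrix:
    """Assign peaks to half-open bins ``[k*w, (k+1)*w)`` anchored at 0 bp.

    A sample scores 1 in a bin if at least one retained peak falls in it.
    Bins occupied by no peak in any sample do not appear (and cannot, since
    bins are created from peaks). All records must share one enzyme.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not records:
        raise ValueError("no peaks to bin")
    enzymes = {r.enzyme for r in records}
    if len(enzymes) != 1:
        raise ValueError(f"mixed-enzyme input rejected: {sorted(enzymes)}")
    enzyme = enzymes.pop()

    sample_ids = sorted({r.sample_id for r in records})
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    ks = np.array([int(np.floor(r.size / bin_width)) for r in records])
    bin_indices = np.unique(ks)
    bin_pos = {int(k): j for j, k in enumerate(bin_indices)}
    presence = np.zeros((len(sample_ids), len(bin_indices)), dtype=np.uint8)
    for r, k in zip(records, ks):
        presence[sample_pos[r.sample_id], bin_pos[int(k)]] = 1
    return BinnedMatrix(sample_ids, bin_indices, float(bin_width), presence, enzyme)


@dataclass
class ConsistencyReport:
    """Run-to-run reproducibility of a control sample's binary profile."""

    control_id: str
    pairs: pd.DataFrame  # run_a, run_b, n_bins, n_mismatch, mismatch_fraction, flagged
    tolerance: float

    @property
    def max_mismatch_fraction(self) -> float:
        return float(self.pairs["mismatch_fraction"].max())

    @property
    def flagged_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["flagged"]]


def check_control_consistency(
    matrices: Mapping[str, BinnedMatrix],
    control_id: str,
    tolerance: float = 0.05,
) -> ConsistencyReport:
    """Compare the control sample's presence profile between runs.

    For every unordered pair of runs, the two control profiles are aligned
    on the union of the runs' occupied bins (a bin absent from a run scores
    0 for the control there) and the fraction of disagreeing bins is
    reported; pairs exceeding ``tolerance`` are flagged.

    Raises
    ------
    KeyError
        The control is absent from some run (the error names the run).
    ValueError
        Fewer than two runs.
    """
    if len(matrices) < 2:
        raise ValueError("control consistency needs >= 2 runs")
    profiles: dict[str, dict[int, int]] = {}
    for run_id, bm in matrices.items():
        if control_id not in bm.sample_ids:
            raise KeyError(f"control sample {control_id!r} absent from run {run_id!r}")
        i = bm.sample_ids.index(control_id)
        profiles[run_id] = dict(zip(bm.bin_indices.tolist(), bm.presence[i].tolist()))

    runs = sorted(profiles)
    rows = []
    for a_i, run_a in enumerate(runs):
        for run_b in runs[a_i + 1:]:
            union = sorted(set(profiles[run_a]) | set(profiles[run_b]))
            a = np.array([profiles[run_a].get(k, 0) for k in union])
            b = np.array([profiles[run_b].get(k, 0) for k in union])
            n_mis = int((a != b).sum())
            frac = n_mis / len(union) if union else 0.0
            rows.append(
                {
                    "run_a": run_a,
                    "run_b": run_b,
                    "n_bins": len(union),
                    "n_mismatch": n_mis,
                    "mismatch_fraction": frac,
                    "flagged": frac > tolerance,
                }
            )
    return ConsistencyReport(control_id, pd.DataFrame(rows), tolerance)
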