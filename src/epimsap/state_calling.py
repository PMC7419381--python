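"""Four-state CCGG methylation calling from paired HpaII/MspI profiles.

The isoschizomers HpaII and MspI both cut CCGG but are blocked by different
cytosine-methylation states, so the joint (MspI, HpaII) presence pattern of
a fragment encodes the methylation state of its CCGG site:

======== ======== =============== =========================================
 MspI     HpaII    call            interpretation
======== ======== =============== =========================================
 (+)      (+)      NONMETH         unmethylated CCGG (both enzymes cut)
 (-)      (-)      FULLMETH        mCmCGG, full methylation (neither cuts)
 (+)      (-)      CG_METH         CmCGG, internal-CG methylation
 (-)      (+)      INDET           ambiguous in plants: mCCGG or CmCGG
======== ======== =============== =========================================

Loci are then partitioned into methylation-susceptible loci (MSL) and
non-methylated loci (NML): a locus is MSL when the frequency of
HpaII/MspI-*discordant* patterns ((+,−) or (−,+)) across non-missing samples
exceeds the scoring error rate (default 0.05, the per-primer-combination
error rate). At NML loci the two profiles agree everywhere, so a (−,−) call
there is read as absence of the band (an ordinary AFLP polymorphism), not
as methylation; at MSL loci (−,−) is full methylation. This is the
convention of the standard MSAP analysis packages and is what makes NML
variation a methylation-insensitive (essentially genetic) control channel.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .peak_io import HPAII, MSPI, BinnedMatrix

__all__ = [
    "MethState",
    "StateMatrix",
    "LocusPartition",
    "call_patterns",
    "classify_loci",
    "state_proportions",
    "methylation_level",
    "binarize",
]


class MethState(enum.IntEnum):
    """Per-cell methylation call; integer codes are the storage format."""

    NONMETH = 0   # (+,+)
    FULLMETH = 1  # (-,-)
    CG_METH = 2   # (+,-)
    INDET = 3     # (-,+)
    MISSING = -1


#: states read as "methylated" when computing methylation levels and the
#: MSL binary fraction
METH_INDICATIVE = (MethState.FULLMETH, MethState.CG_METH, MethState.INDET)
#: states where the HpaII and MspI profiles disagree; their frequency
#: decides MSL vs NML
DISCORDANT = (MethState.CG_METH, MethState.INDET)

STATE_TO_CODE = {
    MethState.NONMETH: "u",
    MethState.FULLMETH: "f",
    MethState.CG_METH: "h",
    MethState.INDET: "i",
    MethState.MISSING: ".",
}
CODE_TO_STATE = {v: k for k, v in STATE_TO_CODE.items()}

STATE_NAMES = {
    MethState.NONMETH: "NONMETH",
    MethState.FULLMETH: "FULLMETH",
    MethState.CG_METH: "CG_METH",
    MethState.INDET: "INDET",
}


def state_from_presence(msp: int, hpa: int) -> MethState:
    """Map a (MspI, HpaII) presence pair to its methylation call."""
    return {
        (1, 1): MethState.NONMETH,
        (0, 0): MethState.FULLMETH,
        (1, 0): MethState.CG_METH,
        (0, 1): MethState.INDET,
    }[(int(msp), int(hpa))]


@dataclass
class StateMatrix:
    """Samples x loci grid of methylation calls plus sample metadata.

    ``calls`` is an int8 array of :class:`MethState` codes. ``metadata`` is
    a DataFrame indexed by sample id; typical columns are ``group``,
    ``site``, ``family``, ``generation``, ``mother``, ``father``, ``mode``.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        valid = {int(s) for s in MethState}
        if not set(np.unique(self.calls)).issubset(valid):
            raise ValueError("calls contain values outside the MethState codes")
        if self.metadata is None:
            self.metadata = pd.DataFrame()
        if len(self.metadata) and not set(self.metadata.index).issubset(self.sample_ids):
            extra = set(self.metadata.index) - set(self.sample_ids)
            raise ValueError(f"metadata samples not in sample_ids: {sorted(extra)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def calls_for(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_index(sample_id)]

    def group_labels(self, grouping: str | Mapping[str, str] | pd.Series) -> pd.Series:
        """Resolve a grouping (metadata column name, dict or Series) to a
        Series over all samples."""
        if isinstance(grouping, str):
            if grouping not in self.metadata.columns:
                raise KeyError(f"metadata column {grouping!r} not found")
            labels = self.metadata[grouping].reindex(self.sample_ids)
        else:
            labels = pd.Series(dict(grouping)).reindex(self.sample_ids)
        if labels.isna().any():
            missing = [s for s, v in labels.items() if pd.isna(v)]
            raise ValueError(f"grouping does not cover samples: {missing[:5]}")
        return labels

    def subset_loci(self, locus_ids: Sequence[str]) -> "StateMatrix":
        pos = [self.locus_ids.index(l) for l in locus_ids]
        return StateMatrix(
            list(self.sample_ids), list(locus_ids), self.calls[:, pos], self.metadata.copy()
        )

    def to_frame(self) -> pd.DataFrame:
        """Character-coded matrix ({u,f,h,i,.}), samples in rows."""
        codes = np.array([STATE_TO_CODE[MethState(v)] for v in range(-1, 4)])
        chars = codes[self.calls + 1]
        return pd.DataFrame(chars, index=self.sample_ids, columns=self.locus_ids)

    def write_tsv(self, path: str | Path, metadata_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")
        if metadata_path is not None and len(self.metadata):
            self.metadata.to_csv(metadata_path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, path: str | Path, metadata_path: str | Path | None = None) -> "StateMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        try:
            calls = np.vectorize(lambda c: int(CODE_TO_STATE[c]))(df.to_numpy())
        except KeyError as exc:
            raise ValueError(f"unknown state code in {path}: {exc}") from exc
        meta = pd.DataFrame()
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
        return cls(
            [str(s) for s in df.index], [str(c) for c in df.columns],
            calls.astype(np.int8), meta,
        )


def call_patterns(hpa: BinnedMatrix, msp: BinnedMatrix) -> StateMatrix:
    """Combine paired per-enzyme presence matrices into a state matrix.

    Loci are the union of the two matrices' occupied bins (a bin occupied
    in only one enzyme's profile is scored absent in the other: a band seen
    only in the MspI profile is precisely the CmCGG signature). Locus order
    is ascending bin position; locus ids are the bin midpoints in bp.

    Raises
    ------
    ValueError
        Enzyme roles swapped, bin widths differ, sample sets differ, or no
        occupied bins at all.
    """
    if hpa.enzyme != HPAII or msp.enzyme != MSPI:
        raise ValueError(f"expected (HpaII, MspI) matrices, got ({hpa.enzyme}, {msp.enzyme})")
    if hpa.bin_width != msp.bin_width:
        raise ValueError("bin widths differ between enzymes")
    if set(hpa.sample_ids) != set(msp.sample_ids):
        raise ValueError("sample sets differ between the HpaII and MspI matrices")

    bins = np.union1d(hpa.bin_indices, msp.bin_indices)
    if bins.size == 0:
        raise ValueError("no occupied bins in either matrix")
    samples = sorted(hpa.sample_ids)

    def aligned(bm: BinnedMatrix) -> np.ndarray:
        out = np.zeros((len(samples), bins.size), dtype=np.uint8)
        col = {int(k): j for j, k in enumerate(bins)}
        rows = [bm.sample_ids.index(s) for s in samples]
        for j_src, k in enumerate(bm.bin_indices):
            out[:, col[int(k)]] = bm.presence[rows, j_src]
        return out

    h = aligned(hpa)
    m = aligned(msp)
    # (msp, hpa): (1,1)->0 (1,0)->2 (0,1)->3 (0,0)->1
    calls = np.where(m == 1, np.where(h == 1, 0, 2), np.where(h == 1, 3, 1)).astype(np.int8)
    locus_ids = [f"{(k + 0.5) * hpa.bin_width:g}" for k in bins]
    return StateMatrix(samples, locus_ids, calls)


@dataclass
class LocusPartition:
    """MSL/NML assignment with per-locus polymorphism flags.

    ``excluded_ids`` holds loci with no non-missing calls (dropped with a
    warning); the MSL and NML lists are disjoint and jointly exhaustive
    over the remaining loci.
    """

    msl_ids: list[str]
    nml_ids: list[str]
    polymorphic: dict[str, bool]
    error_rate: float
    excluded_ids: list[str] = field(default_factory=list)

    def is_msl(self, locus_id: str) -> bool:
        return locus_id in set(self.msl_ids)

    @property
    def n_polymorphic_msl(self) -> int:
        return sum(self.polymorphic[l] for l in self.msl_ids)

    @property
    def n_polymorphic_nml(self) -> int:
        return sum(self.polymorphic[l] for l in self.nml_ids)

    def percent_polymorphic(self, fraction: str) -> float:
        """Percent of MSL (or NML) loci flagged polymorphic."""
        ids = self.msl_ids if fraction.upper() == "MSL" else self.nml_ids
        if not ids:
            raise ValueError(f"no {fraction} loci")
        return 100.0 * sum(self.polymorphic[l] for l in ids) / len(ids)

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "n_msl": len(self.msl_ids),
                "n_nml": len(self.nml_ids),
                "n_excluded": len(self.excluded_ids),
                "n_polymorphic_msl": self.n_polymorphic_msl,
                "n_polymorphic_nml": self.n_polymorphic_nml,
                "error_rate": self.error_rate,
            }
        )


def _state_freqs(calls: np.ndarray) -> np.ndarray:
    """Per-locus frequencies of the four states over non-missing samples.

    Returns an (n_loci, 4) array; rows of all-missing loci are NaN.
    """
    n_loci = calls.shape[1]
    freqs = np.full((n_loci, 4), np.nan)
    nonmiss = calls >= 0
    counts = np.stack([(calls == s).sum(axis=0) for s in range(4)], axis=1).astype(float)
    denom = nonmiss.sum(axis=0).astype(float)
    ok = denom > 0
    freqs[ok] = counts[ok] / denom[ok, None]
    return freqs


def classify_loci(sm: StateMatrix, error_rate: float = 0.05) -> LocusPartition:
    """Partition loci into MSL and NML at the scoring error threshold.

    A locus is MSL iff the frequency of discordant patterns ((+,−) or
    (−,+)) across its non-missing samples exceeds ``error_rate``.
    Polymorphism: an MSL locus is polymorphic if at least two distinct
    states each occur above ``error_rate`` frequency; an NML locus is
    polymorphic if band presence and band absence ((−,−)) both occur above
    ``error_rate`` frequency. All-missing loci are excluded with a warning.
    """
    if sm.n_loci == 0 or sm.n_samples == 0:
        raise ValueError("empty state matrix")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    freqs = _state_freqs(sm.calls)
    msl_ids, nml_ids, excluded = [], [], []
    polymorphic: dict[str, bool] = {}
    for j, locus in enumerate(sm.locus_ids):
        f = freqs[j]
        if np.isnan(f).any():
            excluded.append(locus)
            continue
        discordant = f[MethState.CG_METH] + f[MethState.INDET]
        if discordant > error_rate:
            msl_ids.append(locus)
            polymorphic[locus] = int((f > error_rate).sum()) >= 2
        else:
            nml_ids.append(locus)
            presence = f[MethState.NONMETH] + f[MethState.CG_METH] + f[MethState.INDET]
            absence = f[MethState.FULLMETH]
            polymorphic[locus] = presence > error_rate and absence > error_rate
    if excluded:
        warnings.warn(f"excluded {len(excluded)} all-missing loci", stacklevel=2)
    return LocusPartition(msl_ids, nml_ids, polymorphic, error_rate, excluded)


def _scope_calls(sm: StateMatrix, partition: LocusPartition, scope: str) -> np.ndarray:
    scope = scope.lower()
    if scope in ("msl", "msl-only"):
        ids = partition.msl_ids
    elif scope == "nml":
        ids = partition.nml_ids
    elif scope == "all":
        ids = [l for l in sm.locus_ids if l not in set(partition.excluded_ids)]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if not ids:
        raise ValueError(f"empty scope {scope!r}")
    pos = [sm.locus_ids.index(l) for l in ids]
    return sm.calls[:, pos]


def state_proportions(
    sm: StateMatrix,
    partition: LocusPartition,
    scope: str = "msl",
    per_locus_modal: bool = False,
) -> pd.Series:
    """Proportions of the four states over non-missing cells in scope.

    ``scope`` is 'msl' (default; the usual genome-wide methylation
    breakdown), 'nml', or 'all'. With ``per_locus_modal=True`` each locus
    contributes its modal (most frequent) state once and proportions are
    over loci instead of cells. Proportions sum to 1.
    """
    calls = _scope_calls(sm, partition, scope)
    if per_locus_modal:
        freqs = _state_freqs(calls)
        states = np.nanargmax(freqs, axis=1)
        counts = np.bincount(states, minlength=4).astype(float)
    else:
        counts = np.array([(calls == s).sum() for s in range(4)], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no non-missing cells in scope")
    return pd.Series(counts / total, index=[STATE_NAMES[MethState(s)] for s in range(4)])


def methylation_level(
    sm: StateMatrix,
    partition: LocusPartition,
    grouping: str | Mapping[str, str] | pd.Series | None = None,
    scope: str = "msl",
) -> tuple[pd.Series, float]:
    """Per-group percentage of methylated cells, plus the cross-group mean.

    A cell is methylated when its call is one of the methylation-indicative
    states (FULLMETH, CG_METH, INDET); denominators are non-missing cells
    at the loci in scope. With ``grouping=None`` all samples form one group.
    """
    calls = _scope_calls(sm, partition, scope)
    if grouping is None:
        labels = pd.Series("all", index=sm.sample_ids)
    else:
        labels = sm.group_labels(grouping)
    out = {}
    for g, members in labels.groupby(labels).groups.items():
        rows = [sm.sample_ids.index(s) for s in members]
        sub = calls[rows]
        nonmiss = (sub >= 0).sum()
        if nonmiss == 0:
            raise ValueError(f"group {g!r} has no non-missing cells")
        meth = np.isin(sub, [int(s) for s in METH_INDICATIVE]).sum()
        out[g] = 100.0 * meth / nonmiss
    per_group = pd.Series(out).sort_index()
    return per_group, float(per_group.mean())


def binarize(sm: StateMatrix, partition: LocusPartition, fraction: str = "MSL") -> pd.DataFrame:
    """Binary matrix for downstream statistics (samples x loci, NaN missing).

    MSL fraction: 1 when the call is methylation-indicative (FULLMETH,
    CG_METH or INDET), 0 for NONMETH. NML fraction: band presence — 1 when
    a band appears in at least one profile (any call but FULLMETH), 0 for
    (−,−) band absence.
    """
    fraction = fraction.upper()
    if fraction not in ("MSL", "NML"):
        raise ValueError("fraction must be 'MSL' or 'NML'")
    ids = partition.msl_ids if fraction == "MSL" else partition.nml_ids
    if not ids:
        raise ValueError(f"{fraction} fraction is empty")
    pos = [sm.locus_ids.index(l) for l in ids]
    calls = sm.calls[:, pos]
    if fraction == "MSL":
        values = np.isin(calls, [int(s) for s in METH_INDICATIVE]).astype(float)
    else:
        values = (calls != int(MethState.FULLMETH)).astype(float)
    values[calls < 0] = np.nan
    return pd.DataFrame(values, index=sm.sample_ids, columns=ids)
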