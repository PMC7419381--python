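"""Transgenerational scoring of CCGG methylation states.

Given a state matrix and a pedigree, every offspring locus is classified
relative to its parent(s):

* **inherited** — the offspring's four-state call matches at least one
  parental call;
* **novel** — the offspring carries a methylation-indicative state seen in
  no parent;
* **lost** — the parental methylation is absent from the offspring (the
  offspring is unmethylated and matches no parent).

Matching is on the full four-state call, not on binarized band presence:
the per-state breakdowns of the family comparisons require it. A match can
always be coincidental rather than a true transmission event; the analysis
therefore reports match-based categories only.

Origins are then attributed within families: for F1 offspring of an
F0 mother x F0 father cross, {maternal-only, paternal-only, both-parents,
de novo}; for F2 offspring, the state is traced through the F1 generation
(F0-origin requires presence in both the F0 mother and the F1 mother);
clonal (sucker) offspring are scored by the fraction of loci whose call
matches the mother plant. Per-generation epimutation gain/loss rates are
estimated from the clonal families by maximum likelihood with a bootstrap
over loci.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .popgen import RankTestResults, rank_tests
from .state_calling import METH_INDICATIVE, MethState, StateMatrix, STATE_TO_CODE

__all__ = [
    "Generation",
    "Pedigree",
    "InheritanceClass",
    "F1Origin",
    "F2Origin",
    "score_inheritance",
    "attribute_origin_f1",
    "attribute_origin_f2",
    "inheritance_records",
    "clonal_match",
    "state_inheritance_bias",
    "estimate_epimutation_rates",
    "EpimutationRates",
]

GENERATIONS = ("F0", "F1", "F2", "CLONE_MOTHER", "CLONE_OFFSPRING")


class Generation(str, enum.Enum):
    F0 = "F0"
    F1 = "F1"
    F2 = "F2"
    CLONE_MOTHER = "CLONE_MOTHER"
    CLONE_OFFSPRING = "CLONE_OFFSPRING"


@dataclass
class Pedigree:
    """Family structure: individuals with parent links and generation labels.

    ``table`` columns: ``individual``, ``family``, ``generation`` (one of
    F0/F1/F2/CLONE_MOTHER/CLONE_OFFSPRING), ``mother``, ``father`` (empty
    for founders; father empty for clonal offspring), ``mode`` ('sexual'
    or 'asexual').
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"individual", "family", "generation", "mother", "father", "mode"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        t = self.table.copy()
        for col in ("mother", "father"):
            t[col] = t[col].where(~t[col].isna(), None)
            t[col] = t[col].replace({"": None})
        self.table = t.set_index("individual", drop=False) if t.index.name != "individual" else t
        if self.table["individual"].duplicated().any():
            raise ValueError("duplicate individuals in pedigree")
        bad_gen = set(self.table["generation"]) - set(GENERATIONS)
        if bad_gen:
            raise ValueError(f"unknown generation labels: {sorted(bad_gen)}")
        known = set(self.table["individual"])
        for _, row in self.table.iterrows():
            parents = [p for p in (row["mother"], row["father"]) if p]
            for p in parents:
                if p not in known:
                    raise ValueError(f"parent {p!r} of {row['individual']!r} not in pedigree")
            if row["mode"] == "asexual" and row["generation"] == "CLONE_OFFSPRING":
                if not (row["mother"] and not row["father"]):
                    raise ValueError(f"clonal offspring {row['individual']!r} must have exactly one parent")
            if row["generation"] in ("F1", "F2"):
                # founders (e.g. the improved male crossed to the F1) carry
                # no links; a scored sexual offspring needs both parents
                if bool(row["mother"]) != bool(row["father"]):
                    raise ValueError(
                        f"sexual individual {row['individual']!r} must have two parents or none"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            if state.get(node) == 1:
                raise ValueError(f"pedigree cycle involving {node!r}")
            if state.get(node) == 2:
                return
            state[node] = 1
            row = self.table.loc[node]
            for p in (row["mother"], row["father"]):
                if p:
                    visit(p)
            state[node] = 2

        for ind in self.table["individual"]:
            visit(ind)

    @property
    def families(self) -> list[str]:
        return sorted(self.table["family"].unique())

    def members(self, family: str, generation: str | None = None) -> list[str]:
        t = self.table[self.table["family"] == family]
        if generation is not None:
            t = t[t["generation"] == generation]
        return list(t["individual"])

    def parents_of(self, individual: str) -> tuple[str | None, str | None]:
        row = self.table.loc[individual]
        return row["mother"], row["father"]

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Pedigree":
        t = pd.read_csv(path, sep="\t", dtype=str)
        return cls(t)


class InheritanceClass(enum.IntEnum):
    INHERITED = 0
    NOVEL = 1
    LOST = 2
    EXCLUDED = -1


class F1Origin(str, enum.Enum):
    F0M_ONLY = "F0M_only"
    F0P_ONLY = "F0P_only"
    F0M_P = "F0M+P"
    DE_NOVO = "de_novo"
    UNATTRIBUTABLE = "unattributable"


class F2Origin(str, enum.Enum):
    F0_M = "F0M"          # state traced F0 mother -> F1 mother -> F2
    F0_MP = "F0M+P"       # traced through F1 and matching both F0 parents
    F1_M = "F1M_novel"    # novel in the F1 mother, shared with F2
    F1_P = "F1P"          # shared with the F1 father (improved male)
    F1_MP = "F1M+P"       # shared by both F1 parents but not the F0s
    DE_NOVO = "de_novo"
    UNATTRIBUTABLE = "unattributable"


_MISS = int(MethState.MISSING)
_INDICATIVE = np.array([int(s) for s in METH_INDICATIVE])


def score_inheritance(
    parent_calls: np.ndarray | Sequence[np.ndarray],
    offspring_calls: np.ndarray,
) -> np.ndarray:
    """Per-locus inherited / novel / lost classification.

    ``parent_calls`` is an (n_parents, n_loci) array (one row per parent);
    missing parental calls are ignored per locus. Rules, applied in order:

    1. offspring matches any parent's state -> INHERITED;
    2. otherwise, offspring carries a methylation-indicative state
       (absent from every parent by 1.) -> NOVEL;
    3. otherwise the offspring is unmethylated while every informative
       parent is methylated -> LOST.

    Loci where the offspring call, or every parental call, is missing are
    EXCLUDED. The three classes are mutually exclusive and exhaustive over
    the scored loci.
    """
    P = np.atleast_2d(np.asarray(parent_calls, dtype=np.int8))
    o = np.asarray(offspring_calls, dtype=np.int8)
    if P.shape[1] != o.shape[0]:
        raise ValueError("parents and offspring must share the locus set")
    p_valid = P != _MISS
    informative = p_valid.any(axis=0)
    out = np.full(o.shape[0], int(InheritanceClass.EXCLUDED), dtype=np.int8)
    scored = (o != _MISS) & informative
    match = ((P == o[None, :]) & p_valid).any(axis=0)
    novel = np.isin(o, _INDICATIVE)
    out[scored & match] = int(InheritanceClass.INHERITED)
    out[scored & ~match & novel] = int(InheritanceClass.NOVEL)
    out[scored & ~match & ~novel] = int(InheritanceClass.LOST)
    return out


def attribute_origin_f1(
    f0_mother: np.ndarray | None,
    f0_father: np.ndarray | None,
    f1: np.ndarray,
) -> np.ndarray:
    """Per-locus origin category for an F1 offspring.

    Maternal-only when the F1 state matches the mother and not the father,
    paternal-only symmetrically, both-parents when it matches both (the
    parents agree), de novo otherwise. Loci where a required parental
    profile is absent or missing are 'unattributable' (this also covers an
    entirely absent parent profile, passed as ``None``).
    """
    f1 = np.asarray(f1, dtype=np.int8)
    L = f1.shape[0]
    m = np.full(L, _MISS, dtype=np.int8) if f0_mother is None else np.asarray(f0_mother, dtype=np.int8)
    p = np.full(L, _MISS, dtype=np.int8) if f0_father is None else np.asarray(f0_father, dtype=np.int8)
    out = np.empty(L, dtype=object)
    complete = (f1 != _MISS) & (m != _MISS) & (p != _MISS)
    out[~complete] = F1Origin.UNATTRIBUTABLE
    mm = f1 == m
    pp = f1 == p
    out[complete & mm & pp] = F1Origin.F0M_P
    out[complete & mm & ~pp] = F1Origin.F0M_ONLY
    out[complete & ~mm & pp] = F1Origin.F0P_ONLY
    out[complete & ~mm & ~pp] = F1Origin.DE_NOVO
    return out


def attribute_origin_f2(
    f0_mother: np.ndarray | None,
    f1_mother: np.ndarray,
    f1_father: np.ndarray,
    f2: np.ndarray,
    f0_father: np.ndarray | None = None,
) -> np.ndarray:
    """Per-locus origin category for an F2 offspring.

    The state is traced through the F1 generation: F0-origin categories
    require the F2 state to match the F1 mother *and* the F0 mother
    (plus the F0 father for the both-F0-parents category). A state shared
    with the F1 mother but absent from the F0 generation is F1-maternal
    novel; a state shared with the F1 father (the improved male used in
    the second cross) is F1-paternal; shared with both F1 parents but not
    the F0s is F1 M+P; matching no ancestor is de novo. Loci with missing
    required calls are 'unattributable'.
    """
    f2 = np.asarray(f2, dtype=np.int8)
    L = f2.shape[0]
    f1m = np.asarray(f1_mother, dtype=np.int8)
    f1p = np.asarray(f1_father, dtype=np.int8)
    f0m = np.full(L, _MISS, dtype=np.int8) if f0_mother is None else np.asarray(f0_mother, dtype=np.int8)
    f0p = np.full(L, _MISS, dtype=np.int8) if f0_father is None else np.asarray(f0_father, dtype=np.int8)

    out = np.empty(L, dtype=object)
    # the F1 trio must be complete; the F0 profiles upgrade the category
    complete = (f2 != _MISS) & (f1m != _MISS) & (f1p != _MISS)
    out[~complete] = F2Origin.UNATTRIBUTABLE
    mm = f2 == f1m
    pp = f2 == f1p
    m0 = (f2 == f0m) & (f0m != _MISS)
    p0 = (f2 == f0p) & (f0p != _MISS)

    # traced through the F1 mother
    out[complete & mm & m0 & p0] = F2Origin.F0_MP
    out[complete & mm & m0 & ~p0] = F2Origin.F0_M
    f1_novel = complete & mm & ~m0
    out[f1_novel & pp] = F2Origin.F1_MP
    out[f1_novel & ~pp] = F2Origin.F1_M
    # not through the F1 mother
    out[complete & ~mm & pp] = F2Origin.F1_P
    out[complete & ~mm & ~pp] = F2Origin.DE_NOVO
    # an unscored F0 mother makes the F0-vs-F1M distinction impossible
    unres = complete & mm & (f0m == _MISS)
    out[unres] = F2Origin.UNATTRIBUTABLE
    return out


def _calls_or_none(sm: StateMatrix, individual: str | None) -> np.ndarray | None:
    if individual is None or individual not in sm.sample_ids:
        return None
    return sm.calls_for(individual)


def inheritance_records(sm: StateMatrix, ped: Pedigree) -> pd.DataFrame:
    """Per-locus inheritance records for every offspring in the pedigree.

    Returns a long DataFrame with columns ``family``, ``offspring``,
    ``generation``, ``mode``, ``locus``, ``state`` (offspring call code),
    ``classification`` (inherited/novel/lost) and ``origin`` (the
    generation-appropriate category; for clonal offspring,
    'matches_mother'/'mismatch').
    """
    frames = []
    locus_arr = np.asarray(sm.locus_ids)
    for _, row in ped.table.iterrows():
        ind, gen = row["individual"], row["generation"]
        if gen in ("F0", "CLONE_MOTHER") or not (row["mother"] or row["father"]):
            continue  # founders are parents, not scored offspring
        if ind not in sm.sample_ids:
            warnings.warn(f"offspring {ind!r} absent from state matrix; skipped", stacklevel=2)
            continue
        o = sm.calls_for(ind)
        mother, father = ped.parents_of(ind)
        m = _calls_or_none(sm, mother)
        p = _calls_or_none(sm, father)

        parents = [c for c in (m, p) if c is not None]
        if not parents:
            warnings.warn(f"no parental profiles for {ind!r}; skipped", stacklevel=2)
            continue
        cls = score_inheritance(np.stack(parents), o)

        if gen == "F1":
            origin = attribute_origin_f1(m, p, o)
        elif gen == "F2":
            gm, _ = ped.parents_of(mother) if mother else (None, None)
            gm_calls = _calls_or_none(sm, gm)
            f0p_calls = None
            if mother:
                _, gf = ped.parents_of(mother)
                f0p_calls = _calls_or_none(sm, gf)
            if m is None or p is None:
                origin = np.full(sm.n_loci, F2Origin.UNATTRIBUTABLE, dtype=object)
            else:
                origin = attribute_origin_f2(gm_calls, m, p, o, f0_father=f0p_calls)
        else:  # clonal offspring
            origin = np.where(
                (o == m) & (o != _MISS) & (m != _MISS), "matches_mother", "mismatch"
            ).astype(object)
            origin[(o == _MISS) | (m == _MISS)] = "unattributable"

        cls_names = np.array(["inherited", "novel", "lost", "excluded"])
        frames.append(
            pd.DataFrame(
                {
                    "family": row["family"],
                    "offspring": ind,
                    "generation": gen,
                    "mode": row["mode"],
                    "locus": locus_arr,
                    "state": [STATE_TO_CODE[MethState(int(v))] for v in o],
                    "classification": cls_names[np.where(cls < 0, 3, cls)],
                    "origin": [v.value if isinstance(v, enum.Enum) else v for v in origin],
                }
            )
        )
    if not frames:
        raise ValueError("no scorable offspring in pedigree")
    return pd.concat(frames, ignore_index=True)


def clonal_match(sm: StateMatrix, ped: Pedigree) -> tuple[pd.DataFrame, pd.Series]:
    """Fraction of loci whose call matches the mother plant, per clonal
    offspring, plus the per-family mean.

    Only non-missing shared loci enter the denominator; an offspring with
    zero shared loci raises.
    """
    rows = []
    for _, row in ped.table.iterrows():
        if row["generation"] != "CLONE_OFFSPRING":
            continue
        ind = row["individual"]
        mother = row["mother"]
        o = sm.calls_for(ind)
        m = sm.calls_for(mother)
        shared = (o != _MISS) & (m != _MISS)
        if shared.sum() == 0:
            raise ValueError(f"offspring {ind!r} shares no non-missing loci with its mother")
        frac = float((o[shared] == m[shared]).mean())
        rows.append(
            {
                "family": row["family"],
                "offspring": ind,
                "mother": mother,
                "n_loci": int(shared.sum()),
                "matched_fraction": frac,
            }
        )
    if not rows:
        raise ValueError("pedigree contains no clonal offspring")
    per_offspring = pd.DataFrame(rows)
    per_family = per_offspring.groupby("family")["matched_fraction"].mean()
    return per_offspring, per_family


@dataclass
class BiasResult:
    """State- and family-level comparisons of shared-locus proportions for
    one origin category."""

    origin: str
    by_state: RankTestResults | None
    by_family: RankTestResults | None


def state_inheritance_bias(
    records: pd.DataFrame,
    dunn_adjust: str = "bonferroni",
    min_loci: int = 1,
) -> dict[str, BiasResult]:
    """Test whether origin-category membership is biased by methylation
    state or by family.

    For every origin category ``c`` (excluding 'unattributable'):

    * **by state** — per offspring and per state ``s``, the proportion of
      its loci called ``s`` that fall in category ``c``; distributions are
      compared across the four states (Kruskal-Wallis + Dunn with
      direction flags, the layout of the family-comparison tables);
    * **by family** — per offspring, the overall proportion of loci in
      category ``c``, compared across families.

    Categories with fewer than two populated classes are reported with
    ``None`` in the corresponding slot.
    """
    recs = records[records["classification"] != "excluded"]
    results: dict[str, BiasResult] = {}
    origins = [o for o in recs["origin"].unique() if o != "unattributable"]
    state_codes = ["u", "f", "h", "i"]
    for origin in sorted(origins):
        # by state
        by_state_groups: dict[str, list[float]] = {s: [] for s in state_codes}
        for (_, _), sub in recs.groupby(["family", "offspring"]):
            for s in state_codes:
                at_state = sub[sub["state"] == s]
                if len(at_state) >= min_loci:
                    by_state_groups[s].append(float((at_state["origin"] == origin).mean()))
        by_state_groups = {k: v for k, v in by_state_groups.items() if len(v) > 0}
        by_state = (
            rank_tests(by_state_groups, dunn_adjust=dunn_adjust, anova=False)
            if len(by_state_groups) >= 2
            else None
        )
        # by family
        fam_groups: dict[str, list[float]] = {}
        for (fam, _), sub in recs.groupby(["family", "offspring"]):
            fam_groups.setdefault(str(fam), []).append(float((sub["origin"] == origin).mean()))
        fam_groups = {k: v for k, v in fam_groups.items() if len(v) > 0}
        by_family = (
            rank_tests(fam_groups, dunn_adjust=dunn_adjust, anova=False)
            if len(fam_groups) >= 2
            else None
        )
        results[str(origin)] = BiasResult(str(origin), by_state, by_family)
    return results


@dataclass
class EpimutationRates:
    """Per-generation methylation gain/loss rate estimates from clonal
    families, with percentile bootstrap intervals over loci."""

    gain: float
    loss: float
    gain_ci: tuple[float, float]
    loss_ci: tuple[float, float]
    n_pairs: int
    n_loci: int
    gain_degenerate: bool = False
    loss_degenerate: bool = False


def estimate_epimutation_rates(
    sm: StateMatrix,
    ped: Pedigree,
    n_boot: int = 500,
    ci: float = 0.95,
    seed: int | None = None,
) -> EpimutationRates:
    """Maximum-likelihood per-locus switch rates across one clonal generation.

    Cells are binarized to methylated (FULLMETH/CG_METH/INDET) versus
    unmethylated; over all mother-to-clonal-offspring transmissions, the
    gain rate is the fraction of unmethylated mother cells that became
    methylated in the offspring (the binomial MLE), and symmetrically for
    loss. Percentile bootstrap intervals resample loci. If no transmission
    at risk exists for a rate, it is reported as 0 with a degenerate-flag.
    """
    pairs = [
        (row["mother"], row["individual"])
        for _, row in ped.table.iterrows()
        if row["generation"] == "CLONE_OFFSPRING"
    ]
    if not pairs:
        raise ValueError("pedigree contains no clonal offspring")
    L = sm.n_loci
    n0 = np.zeros(L)
    n01 = np.zeros(L)
    n1 = np.zeros(L)
    n10 = np.zeros(L)
    for mother, off in pairs:
        m = sm.calls_for(mother)
        o = sm.calls_for(off)
        ok = (m != _MISS) & (o != _MISS)
        m_meth = np.isin(m, _INDICATIVE) & ok
        o_meth = np.isin(o, _INDICATIVE) & ok
        n0 += (~m_meth & ok)
        n01 += (~m_meth & ok & o_meth)
        n1 += m_meth
        n10 += (m_meth & ~o_meth)

    def rates(idx: np.ndarray) -> tuple[float, float, bool, bool]:
        s0, s01 = n0[idx].sum(), n01[idx].sum()
        s1, s10 = n1[idx].sum(), n10[idx].sum()
        g_deg = s0 == 0
        l_deg = s1 == 0
        return (
            float(s01 / s0) if s0 > 0 else 0.0,
            float(s10 / s1) if s1 > 0 else 0.0,
            g_deg,
            l_deg,
        )

    all_idx = np.arange(L)
    gain, loss, g_deg, l_deg = rates(all_idx)
    rng = np.random.default_rng(seed)
    boots = np.array(
        [rates(rng.integers(0, L, size=L))[:2] for _ in range(n_boot)]
    )
    alpha = (1.0 - ci) / 2.0
    g_lo, g_hi = np.quantile(boots[:, 0], [alpha, 1.0 - alpha])
    l_lo, l_hi = np.quantile(boots[:, 1], [alpha, 1.0 - alpha])
    no_gain_transitions = n01.sum() == 0
    no_loss_transitions = n10.sum() == 0
    return EpimutationRates(
        gain=gain,
        loss=loss,
        gain_ci=(float(g_lo), float(g_hi)),
        loss_ci=(float(l_lo), float(l_hi)),
        n_pairs=len(pairs),
        n_loci=L,
        gain_degenerate=bool(g_deg or no_gain_transitions),
        loss_degenerate=bool(l_deg or no_loss_transitions),
    )
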