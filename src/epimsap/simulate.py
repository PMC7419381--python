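"""Synthetic MSAP data: populations, pedigrees, and raw peak tables.

Everything the pipeline consumes can be generated here with a known
ground truth, so every stage is testable with no external data:

* :func:`simulate_population` — a state matrix with group structure
  (per-group, per-locus state frequencies perturbed around a shared
  baseline);
* :func:`simulate_pedigree` — sexual (F0 -> F1 -> F2) and clonal
  (mother -> sucker) families with known per-generation methylation
  gain/loss rates;
* :func:`simulate_peak_tables` — paired HpaII/MspI fragment peak tables
  whose round trip through peak filtering, binning and pattern calling
  reconstructs the source state matrix exactly;
* :func:`simulate_partition_fixture` — matrices with an exact, known
  MSL/NML split for worked examples.

States are simulated directly rather than through allele dosage: MSAP
markers are dominant, so band scoring collapses dosage anyway. Default
sizes mirror the study design this package models: 5 groups x 18 samples
x 724 loci for the population survey, and four sexual families (13 F2
offspring each) plus nine clonal families for the inheritance analysis.
The default baseline state frequencies (0.214, 0.463, 0.140, 0.183 for
unmethylated / fully methylated / CG-methylated / indeterminate) follow
the genome-wide proportions reported for the surveyed germplasm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .inheritance import Pedigree
from .peak_io import HPAII, MSPI, PeakRecord
from .state_calling import METH_INDICATIVE, MethState, StateMatrix

__all__ = [
    "SimConfig",
    "simulate_population",
    "simulate_pedigree",
    "simulate_peak_tables",
    "simulate_partition_fixture",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; ``seed`` is mandatory for reproducibility.

    ``divergence`` scales the per-group, per-locus Dirichlet perturbation
    of the baseline state frequencies (0 = all groups identical; larger
    values concentrate groups on different states). ``gain_rate`` and
    ``loss_rate`` are per-generation, per-locus methylation switch
    probabilities. Peak-noise parameters control the synthetic
    electropherograms: size jitter SD in bp (truncated so a peak stays in
    its source bin), the RFU range of true peaks (strictly above the
    100-RFU scoring threshold), and the mean number of spurious
    sub-threshold peaks per profile.
    """

    seed: int
    n_groups: int = 5
    n_samples_per_group: int = 18
    n_loci: int = 724
    baseline_freqs: tuple[float, float, float, float] = (0.2139, 0.4630, 0.1400, 0.1831)
    divergence: float = 0.1
    gain_rate: float = 0.02
    loss_rate: float = 0.05
    sexual_families: int = 4
    f2_per_family: int = 13
    clonal_families: int = 9
    clonal_offspring: tuple[int, ...] = (3, 3, 3, 3, 3, 3, 3, 2, 2)
    size_jitter_sd: float = 0.08
    rfu_min: float = 120.0
    rfu_max: float = 2000.0
    spurious_rate: float = 1.0
    size_window: tuple[float, float] = (150.0, 500.0)
    bin_width: float = 0.5
    ensure_observable: bool = True

    def __post_init__(self) -> None:
        f = np.asarray(self.baseline_freqs, dtype=float)
        if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("baseline_freqs must be a 4-vector of probabilities summing to 1")
        for name in ("gain_rate", "loss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.clonal_offspring) != self.clonal_families:
            raise ValueError("clonal_offspring must list one count per clonal family")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("baseline_freqs", "clonal_offspring", "size_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        for key in ("baseline_freqs", "clonal_offspring", "size_window"):
            d[key] = list(d[key])
        return d


def _draw_states(rng: np.random.Generator, freqs: np.ndarray, n_samples: int) -> np.ndarray:
    """Draw (n_samples, n_loci) states from per-locus frequency rows."""
    cum = np.cumsum(freqs, axis=-1)
    u = rng.random((n_samples, freqs.shape[0]))
    return (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.int8)


def _ensure_observable(states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Guarantee each locus produces >= 1 band in each enzyme's profile.

    A locus scored in real data is, by construction, a band observed in at
    least one sample of at least one profile; a locus fully methylated in
    every sample would simply never have been scored. Loci violating the
    constraint get one random sample set to the unmethylated state.
    """
    msp_band = np.isin(states, (int(MethState.NONMETH), int(MethState.CG_METH)))
    hpa_band = np.isin(states, (int(MethState.NONMETH), int(MethState.INDET)))
    bad = ~(msp_band.any(axis=0) & hpa_band.any(axis=0))
    for j in np.flatnonzero(bad):
        states[rng.integers(0, states.shape[0]), j] = int(MethState.NONMETH)
    return states


def _locus_ids(cfg: SimConfig) -> list[str]:
    start_bin = int(np.floor(cfg.size_window[0] / cfg.bin_width))
    return [f"{(start_bin + j + 0.5) * cfg.bin_width:g}" for j in range(cfg.n_loci)]


def simulate_population(cfg: SimConfig) -> StateMatrix:
    """State matrix with group structure.

    Per group and locus, state frequencies are drawn from a Dirichlet
    centered on the baseline with concentration ``baseline / divergence``
    (``divergence = 0`` means every group uses the baseline exactly);
    samples are then drawn independently. Groups are labelled G1..Gk in a
    ``group`` metadata column. Pure function of the config (same seed,
    same matrix).
    """
    rng = np.random.default_rng(cfg.seed)
    baseline = np.asarray(cfg.baseline_freqs, dtype=float)
    sample_ids, group_labels, blocks = [], [], []
    for g in range(cfg.n_groups):
        name = f"G{g + 1}"
        if cfg.divergence > 0:
            alpha = np.maximum(baseline / cfg.divergence, 1e-6)
            freqs = rng.dirichlet(alpha, size=cfg.n_loci)
        else:
            freqs = np.tile(baseline, (cfg.n_loci, 1))
        states = _draw_states(rng, freqs, cfg.n_samples_per_group)
        blocks.append(states)
        ids = [f"{name}_S{i + 1:02d}" for i in range(cfg.n_samples_per_group)]
        sample_ids.extend(ids)
        group_labels.extend([name] * cfg.n_samples_per_group)
    calls = np.concatenate(blocks, axis=0)
    if cfg.ensure_observable:
        calls = _ensure_observable(calls, rng)
    meta = pd.DataFrame({"group": group_labels}, index=sample_ids)
    return StateMatrix(sample_ids, _locus_ids(cfg), calls, meta)


def _apply_switches(states: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One generation of methylation gain/loss on a state vector."""
    out = states.copy()
    meth = np.isin(out, [int(s) for s in METH_INDICATIVE])
    lose = meth & (rng.random(out.shape) < cfg.loss_rate)
    out[lose] = int(MethState.NONMETH)
    gain = (states == int(MethState.NONMETH)) & (rng.random(out.shape) < cfg.gain_rate)
    if gain.any():
        meth_freqs = np.asarray(cfg.baseline_freqs[1:], dtype=float)
        meth_freqs = meth_freqs / meth_freqs.sum()
        new_states = rng.choice(
            [int(s) for s in METH_INDICATIVE], size=int(gain.sum()), p=meth_freqs
        )
        out[gain] = new_states
    return out


def _cross(mother: np.ndarray, father: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    pick_mother = rng.random(mother.shape[0]) < 0.5
    child = np.where(pick_mother, mother, father).astype(np.int8)
    return _apply_switches(child, cfg, rng)


def simulate_pedigree(cfg: SimConfig) -> tuple[StateMatrix, Pedigree]:
    """Sexual and clonal families with known switch rates.

    Sexual families: founder F0 mother and father states are drawn from
    the baseline frequencies; each F1 inherits, per locus, the state of a
    uniformly chosen parent and then undergoes gain/loss switches; F2
    offspring come from crossing the F1 (as mother) with a separate
    founder male. Clonal families: offspring copy the mother's states and
    apply switches. Generation labels and parent links are returned as a
    :class:`~epimsap.inheritance.Pedigree`.
    """
    rng = np.random.default_rng(cfg.seed)
    baseline = np.asarray(cfg.baseline_freqs, dtype=float)
    freqs = np.tile(baseline, (cfg.n_loci, 1))

    # founders are drawn first (and made observable before propagation, so
    # that offspring inherit the fix and parent-offspring closure holds)
    n_founders = 3 * cfg.sexual_families + cfg.clonal_families
    founders = _draw_states(rng, freqs, max(n_founders, 1))
    if cfg.ensure_observable and n_founders:
        founders = _ensure_observable(founders, rng)
    founder_iter = iter(founders)

    ids: list[str] = []
    calls: list[np.ndarray] = []
    ped_rows: list[dict] = []

    def add(ind: str, states: np.ndarray, family: str, generation: str,
            mother: str | None, father: str | None, mode: str) -> None:
        ids.append(ind)
        calls.append(states)
        ped_rows.append(
            {
                "individual": ind,
                "family": family,
                "generation": generation,
                "mother": mother,
                "father": father,
                "mode": mode,
            }
        )

    for f in range(cfg.sexual_families):
        fam = f"SexFam{f + 1}"
        f0m = next(founder_iter)
        f0p = next(founder_iter)
        add(f"{fam}_F0M", f0m, fam, "F0", None, None, "sexual")
        add(f"{fam}_F0P", f0p, fam, "F0", None, None, "sexual")
        f1 = _cross(f0m, f0p, cfg, rng)
        add(f"{fam}_F1", f1, fam, "F1", f"{fam}_F0M", f"{fam}_F0P", "sexual")
        f2p = next(founder_iter)
        add(f"{fam}_F1P", f2p, fam, "F1", None, None, "sexual")
        for i in range(cfg.f2_per_family):
            f2 = _cross(f1, f2p, cfg, rng)
            add(f"{fam}_F2_{i + 1:02d}", f2, fam, "F2", f"{fam}_F1", f"{fam}_F1P", "sexual")

    for f in range(cfg.clonal_families):
        fam = f"CloneFam{f + 1}"
        mother = next(founder_iter)
        add(f"{fam}_M", mother, fam, "CLONE_MOTHER", None, None, "asexual")
        for i in range(cfg.clonal_offspring[f]):
            child = _apply_switches(mother, cfg, rng)
            add(f"{fam}_C{i + 1}", child, fam, "CLONE_OFFSPRING", f"{fam}_M", None, "asexual")

    states = np.stack(calls)
    ped = Pedigree(pd.DataFrame(ped_rows))
    meta = ped.table.set_index("individual")[["family", "generation", "mother", "father", "mode"]]
    meta = meta.reindex(ids)
    sm = StateMatrix(ids, _locus_ids(cfg), states, meta)
    return sm, ped


def simulate_peak_tables(
    sm: StateMatrix, cfg: SimConfig
) -> dict[str, list[PeakRecord]]:
    """Paired HpaII/MspI peak tables realizing a state matrix.

    Loci map to consecutive 0.5-bp bins from the lower edge of the size
    window; each present band becomes one peak at the bin midpoint plus
    Gaussian size jitter truncated at +/- 0.45 bin widths (so a peak never
    leaves its source bin) and an RFU drawn strictly above the scoring
    threshold. Spurious sub-threshold peaks (RFU in (0, 100)) are added at
    ``spurious_rate`` expected peaks per profile. Feeding the output
    through peak filtering, binning and pattern calling reconstructs the
    non-missing cells of ``sm`` exactly. Byte-identical for a given seed.

    Raises
    ------
    ValueError
        More loci than bins fit in the size window: one peak table models
        a single primer combination, which bounds the scorable loci by
        (window width / bin width).
    """
    n_bins_avail = int((cfg.size_window[1] - cfg.size_window[0]) / cfg.bin_width)
    if sm.n_loci > n_bins_avail:
        raise ValueError(
            f"{sm.n_loci} loci exceed the {n_bins_avail} bins available in the size "
            "window; a peak table models one primer combination"
        )
    import warnings as _warnings

    if cfg.size_jitter_sd >= cfg.bin_width:
        _warnings.warn("size jitter SD >= bin width: reconstruction not guaranteed", stacklevel=2)

    rng = np.random.default_rng(cfg.seed)
    start_bin = int(np.floor(cfg.size_window[0] / cfg.bin_width))
    midpoints = (start_bin + np.arange(sm.n_loci) + 0.5) * cfg.bin_width

    band = {
        MSPI: np.isin(sm.calls, (int(MethState.NONMETH), int(MethState.CG_METH))),
        HPAII: np.isin(sm.calls, (int(MethState.NONMETH), int(MethState.INDET))),
    }
    half = 0.45 * cfg.bin_width
    tables: dict[str, list[PeakRecord]] = {}
    for enzyme in (HPAII, MSPI):
        records: list[PeakRecord] = []
        for i, sample in enumerate(sm.sample_ids):
            js = np.flatnonzero(band[enzyme][i])
            jitter = np.clip(rng.normal(0.0, cfg.size_jitter_sd, size=js.size), -half, half)
            sizes = midpoints[js] + jitter
            heights = rng.uniform(cfg.rfu_min, cfg.rfu_max, size=js.size)
            for sz, h in zip(sizes, heights):
                records.append(PeakRecord(sample, enzyme, "run1", float(sz), float(h)))
            n_spur = rng.poisson(cfg.spurious_rate)
            if n_spur:
                spur_sizes = rng.uniform(*cfg.size_window, size=n_spur)
                spur_heights = rng.uniform(5.0, 95.0, size=n_spur)
                for sz, h in zip(spur_sizes, spur_heights):
                    records.append(PeakRecord(sample, enzyme, "run1", float(sz), float(h)))
        tables[enzyme] = records
    return tables


def simulate_partition_fixture(
    n_samples: int = 90,
    n_msl: int = 622,
    n_nml: int = 102,
    min_discordant: float = 0.10,
    nml_segregating: bool = False,
    error_rate: float = 0.05,
    seed: int = 0,
) -> StateMatrix:
    """State matrix with an exact, known MSL/NML partition.

    MSL loci draw states from the baseline frequency profile but are
    guaranteed at least ``min_discordant`` of samples in a
    HpaII/MspI-discordant state (so they classify as
    methylation-susceptible at any error rate below ``min_discordant``).
    NML loci carry only concordant patterns: with
    ``nml_segregating=False`` the band is present ((+,+)) in every sample;
    with ``True`` every NML locus segregates for band presence versus
    absence ((−,−)), both states guaranteed above ``error_rate``
    frequency.
    """
    rng = np.random.default_rng(seed)
    n_loci = n_msl + n_nml
    calls = np.empty((n_samples, n_loci), dtype=np.int8)

    min_disc_count = int(np.ceil(min_discordant * n_samples))
    for j in range(n_msl):
        n_disc = int(rng.integers(min_disc_count, n_samples + 1))
        states = np.concatenate(
            [
                rng.choice([int(MethState.CG_METH), int(MethState.INDET)], size=n_disc),
                rng.choice(
                    [int(MethState.NONMETH), int(MethState.FULLMETH)],
                    size=n_samples - n_disc,
                ),
            ]
        ).astype(np.int8)
        calls[:, j] = rng.permutation(states)

    min_seg = int(np.floor(error_rate * n_samples)) + 1
    for j in range(n_msl, n_loci):
        if nml_segregating:
            n_present = int(rng.integers(min_seg, n_samples - min_seg + 1))
            states = np.concatenate(
                [
                    np.full(n_present, int(MethState.NONMETH)),
                    np.full(n_samples - n_present, int(MethState.FULLMETH)),
                ]
            ).astype(np.int8)
            calls[:, j] = rng.permutation(states)
        else:
            calls[:, j] = int(MethState.NONMETH)

    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    locus_ids = [f"L{j + 1:04d}" for j in range(n_loci)]
    return StateMatrix(sample_ids, locus_ids, calls)
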