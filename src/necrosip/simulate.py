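"""Synthetic data with the statistical structure the analysis assumes.

Two generators stand in for the study's raw measurements so every stage of
the pipeline is testable at desk scale:

* :func:`simulate_counts` — multi-treatment 16S amplicon libraries from a
  Dirichlet-multinomial community with log-normal per-sample overdispersion,
  with responder and sulfate-reducer effects planted multiplicatively on the
  underlying composition (so shifts propagate compositionally, as in real
  relative-abundance data).
* :func:`simulate_spectra` — single-cell Raman spectra as polynomial
  baseline + two phenylalanine Gaussians (1002 cm-1 for 12C, 965 cm-1 for
  13C) + noise, where labeling moves a per-cell share ``s`` of the band mass
  from the 12C to the 13C position.

Both return their ground truth alongside the data and are fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountTable, SampleMetadata, SpectrumSet, ValidationError

__all__ = [
    "PlantedResponder",
    "PlantedSRM",
    "CommunitySimConfig",
    "PopulationSpec",
    "SpectraSimConfig",
    "default_design",
    "default_community_config",
    "default_spectra_config",
    "simulate_counts",
    "simulate_spectra",
]

DEFAULT_DAYS = (0, 13, 20, 32)  # subset of the incubation's sampling days
FULL_DAYS = (0, 4, 8, 13, 20, 25, 32, 39)


@dataclass(frozen=True)
class PlantedResponder:
    """A phylotype that responds to one substrate from ``onset_day`` on.

    The fold changes multiply the phylotype's underlying proportion in
    substrate-amended samples: ``fold_dna`` in 16S gene (DNA) libraries,
    ``fold_rna`` in transcript (RNA) libraries.  Responders keep responding
    under molybdate (fermenters are not sulfate reducers).
    """

    phylotype: int
    substrate: str
    fold_dna: float
    fold_rna: float
    onset_day: int = 13

    def __post_init__(self) -> None:
        if self.fold_dna <= 0 or self.fold_rna <= 0:
            raise ValidationError("fold changes must be positive")


@dataclass(frozen=True)
class PlantedSRM:
    """A sulfate reducer suppressed ``suppression``-fold under molybdate."""

    phylotype: int
    suppression: float

    def __post_init__(self) -> None:
        if self.suppression <= 0:
            raise ValidationError("suppression factor must be positive")


@dataclass(frozen=True)
class CommunitySimConfig:
    n_phylotypes: int = 2000
    library_depth: int = 4732
    depth_dispersion: float = 0.1
    base_concentration: float = 0.3  # per-phylotype Dirichlet alpha
    overdispersion_sigma: float = 0.2  # per-sample log-normal noise
    design: pd.DataFrame | None = None
    planted_responders: tuple[PlantedResponder, ...] = ()
    planted_srm: tuple[PlantedSRM, ...] = ()
    planted_baseline_range: tuple[float, float] | None = (0.002, 0.01)
    srm_baseline_range: tuple[float, float] | None = (0.005, 0.02)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phylotypes < 1 or self.library_depth < 1:
            raise ValidationError("n_phylotypes and library_depth must be positive")
        if self.base_concentration <= 0 or self.overdispersion_sigma < 0:
            raise ValidationError("invalid community parameters")
        for planted in (*self.planted_responders, *self.planted_srm):
            if not 0 <= planted.phylotype < self.n_phylotypes:
                raise ValidationError(f"planted index {planted.phylotype} out of range")


def default_design(
    days: Sequence[int] = DEFAULT_DAYS,
    doses: Sequence[str] = ("LD", "HD"),
    substrates: Sequence[str] = ("spirulina", "acetate"),
    molecules: Sequence[str] = ("DNA", "RNA"),
    with_molybdate: bool = True,
) -> pd.DataFrame:
    """Metadata table emulating the incubation design: substrate x dose x
    (+-molybdate) x day x molecule plus the unamended control series."""
    rows = []
    for day in days:
        for molecule in molecules:
            rows.append(
                dict(
                    sample_id=f"none-d{day:02d}-{molecule}",
                    day=day, substrate="none", isotope="none", dose="none",
                    inhibitor="none", molecule=molecule, replicate=1,
                )
            )
    for substrate in substrates:
        for dose in doses:
            inhibitors = ("none", "molybdate") if with_molybdate else ("none",)
            for inhibitor in inhibitors:
                tag = "-mo" if inhibitor == "molybdate" else ""
                for day in days:
                    for molecule in molecules:
                        rows.append(
                            dict(
                                sample_id=f"{substrate[:4]}-{dose}{tag}-d{day:02d}-{molecule}",
                                day=day, substrate=substrate, isotope="13C",
                                dose=dose, inhibitor=inhibitor,
                                molecule=molecule, replicate=1,
                            )
                        )
    return pd.DataFrame(rows)


def default_community_config(
    seed: int = 0,
    *,
    n_responders: int = 10,
    n_srm: int = 5,
    fold: float = 8.0,
    suppression: float = 10.0,
    onset_day: int = 13,
    rna_only_fraction: float = 0.0,
    **overrides,
) -> CommunitySimConfig:
    """Study-condition defaults with ``n_responders`` substrate responders
    (alternating spirulina/acetate) and ``n_srm`` molybdate-suppressed
    sulfate reducers planted on distinct phylotypes.

    ``rna_only_fraction`` makes that share of responders activity-only
    (fold applied to RNA libraries only), mirroring phylotypes that respond
    by ribosomal activity without growth.
    """
    base = CommunitySimConfig(seed=seed, **overrides)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    picks = rng.choice(base.n_phylotypes, size=n_responders + n_srm, replace=False)
    responders = []
    n_rna_only = int(round(rna_only_fraction * n_responders))
    for k in range(n_responders):
        substrate = "spirulina" if k % 2 == 0 else "acetate"
        fold_dna = 1.0 if k < n_rna_only else fold
        responders.append(
            PlantedResponder(int(picks[k]), substrate, fold_dna, fold, onset_day)
        )
    srm = [PlantedSRM(int(p), suppression) for p in picks[n_responders:]]
    return replace(
        base, planted_responders=tuple(responders), planted_srm=tuple(srm)
    )


def _phylotype_ids(n: int) -> list[str]:
    return [f"p{i:04d}" for i in range(n)]


def simulate_counts(
    config: CommunitySimConfig,
) -> tuple[CountTable, SampleMetadata, pd.DataFrame]:
    """Draw a count table, its metadata and the planted-effect ground truth.

    Baseline composition ~ Dirichlet (drawn once); planted phylotypes are
    re-assigned baseline proportions from ``planted_baseline_range`` so
    effects act on detectably abundant community members; each sample
    perturbs the composition log-normally, applies the planted multipliers,
    renormalizes, and draws reads multinomially at a depth drawn around
    ``library_depth``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_phylotypes
    design = config.design if config.design is not None else default_design()
    meta = SampleMetadata(design)

    base = rng.dirichlet(np.full(n, config.base_concentration))
    # planted phylotypes are re-seated at detectably abundant baselines; the
    # inhibition contrast in particular is information-bounded by the
    # uninhibited count, so sulfate reducers (abundant taxa in sulfidic
    # sediments) draw from a higher range than substrate responders
    srm_idx = sorted({p.phylotype for p in config.planted_srm})
    resp_idx = sorted(
        {p.phylotype for p in config.planted_responders} - set(srm_idx)
    )
    assignments: list[tuple[list[int], tuple[float, float] | None]] = [
        (resp_idx, config.planted_baseline_range),
        (srm_idx, config.srm_baseline_range),
    ]
    planted_idx = [i for idx, rng_ in assignments if rng_ is not None for i in idx]
    if planted_idx:
        base = base.copy()
        assigned = np.concatenate(
            [
                rng.uniform(*rng_, size=len(idx))
                for idx, rng_ in assignments
                if rng_ is not None and idx
            ]
        )
        others = np.setdiff1d(np.arange(n), planted_idx)
        base[others] *= (1.0 - assigned.sum()) / base[others].sum()
        base[planted_idx] = assigned

    ids = _phylotype_ids(n)
    columns = {}
    for _, row in meta.table.iterrows():
        w = base * np.exp(rng.normal(0.0, config.overdispersion_sigma, size=n))
        for resp in config.planted_responders:
            if (
                row["substrate"] == resp.substrate
                and row["day"] >= resp.onset_day
            ):
                fold = resp.fold_dna if row["molecule"] == "DNA" else resp.fold_rna
                w[resp.phylotype] *= fold
        if row["inhibitor"] == "molybdate":
            for srm in config.planted_srm:
                w[srm.phylotype] /= srm.suppression
        w /= w.sum()
        depth = max(
            1,
            int(
                round(
                    rng.normal(
                        config.library_depth,
                        config.library_depth * config.depth_dispersion,
                    )
                )
            ),
        )
        columns[row["sample_id"]] = rng.multinomial(depth, w)

    table = CountTable(
        pd.DataFrame(columns, index=pd.Index(ids, name="phylotype_id"))
    )
    truth_rows = [
        dict(
            phylotype_id=ids[r.phylotype],
            kind="responder",
            substrate=r.substrate,
            fold_dna=r.fold_dna,
            fold_rna=r.fold_rna,
            onset_day=r.onset_day,
            suppression=np.nan,
        )
        for r in config.planted_responders
    ] + [
        dict(
            phylotype_id=ids[s.phylotype],
            kind="srm",
            substrate="",
            fold_dna=np.nan,
            fold_rna=np.nan,
            onset_day=np.nan,
            suppression=s.suppression,
        )
        for s in config.planted_srm
    ]
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "phylotype_id", "kind", "substrate", "fold_dna", "fold_rna",
            "onset_day", "suppression",
        ],
    )
    return table, meta, truth


# ---------------------------------------------------------------------------
# spectra


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    n_cells: int
    labeled_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.labeled_fraction <= 1:
            raise ValidationError("labeled_fraction must be in [0, 1]")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")


@dataclass(frozen=True)
class SpectraSimConfig:
    populations: tuple[PopulationSpec, ...]
    wavenumber_start: float = 600.0
    wavenumber_stop: float = 1800.0
    wavenumber_step: float = 1.0
    center_12c: float = 1002.0
    center_13c: float = 965.0
    peak_fwhm: float = 4.0
    peak_amplitude: float = 1.0
    label_share_range: tuple[float, float] = (0.2, 0.8)
    baseline_degree: int = 5
    baseline_amplitude: float = 0.5
    noise_sigma: float = 0.01
    jitter_max: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValidationError("at least one population required")
        if not 960 <= self.center_13c <= 970 or not 1000 <= self.center_12c <= 1005:
            raise ValidationError("peak centers must lie inside the analysis windows")
        lo, hi = self.label_share_range
        if not 0 < lo <= hi <= 1:
            raise ValidationError("label_share_range must lie in (0, 1]")
        if self.baseline_degree > 5:
            raise ValidationError("baseline degree must be <= 5")
        if self.jitter_max < 0 or self.noise_sigma < 0:
            raise ValidationError("jitter and noise must be non-negative")


def default_spectra_config(
    seed: int = 0,
    *,
    n_cells: int = 100,
    fractions: dict[str, float] | None = None,
    n_negative: int | None = None,
    **overrides,
) -> SpectraSimConfig:
    """One population per requested labeled fraction plus a 12C negative control."""
    fractions = fractions if fractions is not None else {"probe": 0.5}
    pops = [PopulationSpec(name, n_cells, f) for name, f in fractions.items()]
    pops.append(PopulationSpec("negative", n_negative or n_cells, 0.0))
    return SpectraSimConfig(populations=tuple(pops), seed=seed, **overrides)


def _gaussian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / 2.354820045
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def simulate_spectra(
    config: SpectraSimConfig,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Draw single-cell spectra and their per-cell ground truth.

    Each cell is baseline + A[(1-s) G(1002) + s G(965)] + noise with a
    shared per-cell axis jitter on both peak centers; s = 0 for unlabeled
    cells, s ~ Uniform(label_share_range) for labeled cells.  Raw
    intensities are clamped at 0 (detector counts are non-negative).
    """
    rng = np.random.default_rng(config.seed)
    wn = np.arange(
        config.wavenumber_start,
        config.wavenumber_stop + 0.5 * config.wavenumber_step,
        config.wavenumber_step,
    )
    t = (wn - wn.mean()) / (0.5 * (wn[-1] - wn[0]))  # scaled to [-1, 1]
    cell_ids: list[str] = []
    populations: list[str] = []
    spectra: list[np.ndarray] = []
    truth_rows = []
    for pop in config.populations:
        n_labeled = int(round(pop.labeled_fraction * pop.n_cells))
        for j in range(pop.n_cells):
            labeled = j < n_labeled
            s = (
                float(rng.uniform(*config.label_share_range)) if labeled else 0.0
            )
            jitter = float(rng.uniform(-config.jitter_max, config.jitter_max))
            coeffs = rng.normal(
                0.0,
                config.baseline_amplitude / (1.0 + np.arange(config.baseline_degree + 1)),
            )
            baseline = np.polynomial.polynomial.polyval(t, coeffs)
            baseline += config.baseline_amplitude - baseline.min()  # keep positive
            peaks = config.peak_amplitude * (
                (1.0 - s) * _gaussian(wn, config.center_12c + jitter, config.peak_fwhm)
                + s * _gaussian(wn, config.center_13c + jitter, config.peak_fwhm)
            )
            noise = rng.normal(0.0, config.noise_sigma, size=wn.size)
            cid = f"{pop.name}_c{j:03d}"
            cell_ids.append(cid)
            populations.append(pop.name)
            spectra.append(np.clip(baseline + peaks + noise, 0.0, None))
            truth_rows.append(
                dict(cell_id=cid, population=pop.name, labeled=labeled,
                     label_share=s, jitter=jitter)
            )
    spectrum_set = SpectrumSet(wn, np.vstack(spectra), cell_ids, populations)
    return spectrum_set, pd.DataFrame(truth_rows)
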