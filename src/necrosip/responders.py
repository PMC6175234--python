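"""Detection of substrate-responsive and sulfate-reduction-associated phylotypes.

The core inference of the pipeline.  A phylotype counts as *responsive* to a
substrate when it is significantly enriched (one-sided pooled two-proportion
test, Benjamini-Hochberg corrected, adjusted p <= alpha) in at least
``min_libraries`` treatment-vs-control library pairs, pooling evidence across
16S rRNA gene (DNA) and transcript (RNA) libraries.  DNA-level enrichment is
read as *growth* of the population, RNA-only enrichment as increased
ribosomal *activity*.  Phylotypes enriched in uninhibited relative to
molybdate-inhibited incubations are flagged as putative sulfate-reducing
microorganisms (SRM), because molybdate selectively shuts down sulfate
reduction.  The three boolean axes (spirulina-responsive, acetate-responsive,
SRM) then map deterministically onto functional guilds of the anaerobic
carbon-degradation cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AnalysisConfig, CountTable, SampleMetadata, ValidationError
from .stats import TestResult, bh_adjust, two_proportion_z, wilcoxon_rank_sum

__all__ = [
    "ContrastPair",
    "build_substrate_contrasts",
    "build_inhibition_contrasts",
    "relative_abundance",
    "test_enrichment",
    "test_inhibition",
    "classify_guilds",
    "compare_rates",
    "ResponderModel",
    "ResponderResults",
]

GUILDS = (
    "hydrolyser_fermenter",
    "acetate_utilizing_srm",
    "srm_other_donor",
    "vfa_utilizer_non_srm",
    "unclassified",
)


@dataclass(frozen=True)
class ContrastPair:
    """One treatment library paired with its control library."""

    treatment: str
    control: str


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample relative abundances: each column divided by its read total."""
    depths = table.sample_depths()
    zero = depths[depths == 0]
    if len(zero):
        raise ValidationError(f"zero-sum sample(s): {list(zero.index)}")
    return table.counts / depths


def _match_control(
    meta: SampleMetadata, day: int, molecule: str, replicate: int, **criteria
) -> str | None:
    candidates = meta.select(day=day, molecule=molecule, **criteria)
    if candidates.empty:
        return None
    exact = candidates[candidates["replicate"] == replicate]
    row = exact.iloc[0] if not exact.empty else candidates.iloc[0]
    return str(row["sample_id"])


def build_substrate_contrasts(
    meta: SampleMetadata,
    substrate: Literal["spirulina", "acetate"],
    *,
    dose: str = "HD",
    isotope: str = "13C",
    days: Sequence[int] | None = None,
    molecules: Sequence[str] = ("DNA", "RNA"),
) -> list[ContrastPair]:
    """Pair substrate-amended libraries with the no-substrate control.

    The default pairing matches each uninhibited treatment library to the
    unamended control sampled on the same day with the same molecule
    (replicate-matched when possible).  With two sampling days and both
    molecules this yields the n = 4 library pairs of the substrate analysis.
    ``days=None`` selects the two latest days with treatment libraries.
    """
    treat = meta.select(substrate=substrate, dose=dose, isotope=isotope, inhibitor="none")
    if treat.empty:
        raise ValidationError(f"no {substrate} {dose} {isotope} libraries in metadata")
    if days is None:
        days = sorted(treat["day"].unique())[-2:]
    pairs: list[ContrastPair] = []
    for _, row in treat[treat["day"].isin(list(days))].iterrows():
        ctrl = _match_control(
            meta, int(row["day"]), str(row["molecule"]), int(row["replicate"]),
            substrate="none",
        )
        if ctrl is None:
            raise ValidationError(
                f"no unamended control for day {row['day']} {row['molecule']}"
            )
        if str(row["molecule"]) not in molecules:
            continue
        pairs.append(ContrastPair(str(row["sample_id"]), ctrl))
    return pairs


def build_inhibition_contrasts(
    meta: SampleMetadata,
    *,
    dose: str = "HD",
    isotope: str = "13C",
    days: Sequence[int] | None = None,
    substrates: Sequence[str] = ("spirulina", "acetate"),
    molecules: Sequence[str] = ("DNA", "RNA"),
) -> list[ContrastPair]:
    """Pair uninhibited substrate libraries (treatment) with molybdate-inhibited
    libraries (control) matched by substrate, dose, day and molecule.

    Across two substrates, two days and both molecules this yields the n = 8
    library pairs of the sulfate-reduction analysis.
    """
    pairs: list[ContrastPair] = []
    for substrate in substrates:
        treat = meta.select(substrate=substrate, dose=dose, isotope=isotope, inhibitor="none")
        if treat.empty:
            continue
        use_days = sorted(treat["day"].unique())[-2:] if days is None else days
        for _, row in treat[treat["day"].isin(list(use_days))].iterrows():
            if str(row["molecule"]) not in molecules:
                continue
            ctrl = _match_control(
                meta, int(row["day"]), str(row["molecule"]), int(row["replicate"]),
                substrate=substrate, dose=dose, inhibitor="molybdate",
            )
            if ctrl is None:
                raise ValidationError(
                    f"no molybdate-inhibited control for {substrate} day {row['day']}"
                    f" {row['molecule']}"
                )
            pairs.append(ContrastPair(str(row["sample_id"]), ctrl))
    if not pairs:
        raise ValidationError("no uninhibited/inhibited library pairs found")
    return pairs


def _enrichment_records(
    table: CountTable,
    meta: SampleMetadata,
    pairs: Sequence[ContrastPair],
    config: AnalysisConfig,
    *,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-phylotype, per-library-pair enrichment tests.

    One-sided (greater) pooled two-proportion test of the phylotype's count
    in the treatment library against its paired control, BH-adjusted across
    all phylotypes within each library pair.  Phylotypes absent from both
    libraries of a pair get p = 1 and stay in the family, keeping the BH
    family size stable.
    """
    counts = table.counts
    depths = table.sample_depths()
    meta.validate_against(table)
    for pair in pairs:
        for sid in (pair.treatment, pair.control):
            if sid not in counts.columns:
                raise ValidationError(f"contrast references unknown sample {sid!r}")
    mol = meta.table["molecule"]
    frames = []
    keep = np.ones(counts.shape[0], dtype=bool)
    if config.min_abundance > 0:
        used = sorted({s for p in pairs for s in (p.treatment, p.control)})
        rel = counts[used] / depths[used]
        keep = (rel.max(axis=1) >= config.min_abundance).to_numpy()
    for pair in pairs:
        if mol[pair.treatment] != mol[pair.control]:
            raise ValidationError(
                f"pair {pair.treatment}/{pair.control} mixes DNA and RNA libraries"
            )
        x_t = counts[pair.treatment].to_numpy(float)
        x_c = counts[pair.control].to_numpy(float)
        n_t = float(depths[pair.treatment])
        n_c = float(depths[pair.control])
        z = two_proportion_z(x_t, n_t, x_c, n_c, continuity=config.continuity_correction)
        raw_p = sps.norm.sf(z)
        raw_p[x_t / n_t == x_c / n_c] = 1.0  # identical proportions: no evidence
        raw_p[~keep] = 1.0
        adj_p = raw_p.copy()
        if adjust:
            adj_p[keep] = bh_adjust(raw_p[keep])
        enriched = (adj_p <= config.alpha) & (x_t / n_t > x_c / n_c) & keep
        frames.append(
            pd.DataFrame(
                {
                    "phylotype_id": counts.index,
                    "treatment": pair.treatment,
                    "control": pair.control,
                    "molecule": mol[pair.treatment],
                    "x_treat": x_t.astype(int),
                    "n_treat": int(n_t),
                    "x_ctrl": x_c.astype(int),
                    "n_ctrl": int(n_c),
                    "statistic": z,
                    "raw_p": raw_p,
                    "adj_p": adj_p,
                    "enriched": enriched,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _aggregate_calls(records: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Collapse per-pair enrichment into per-phylotype responder calls."""
    is_dna = records["molecule"] == "DNA"
    grouped = records.assign(
        dna_hit=records["enriched"] & is_dna,
        rna_hit=records["enriched"] & ~is_dna,
    ).groupby("phylotype_id", sort=False)
    calls = grouped.agg(
        n_enriched_dna=("dna_hit", "sum"),
        n_enriched_rna=("rna_hit", "sum"),
        min_adj_p=("adj_p", "min"),
    ).reset_index()
    total = calls["n_enriched_dna"] + calls["n_enriched_rna"]
    calls["responsive"] = total >= config.min_libraries
    mode = np.where(
        ~calls["responsive"],
        "none",
        np.where(calls["n_enriched_dna"] >= 1, "growth", "activity"),
    )
    calls["response_mode"] = mode
    return calls


def test_enrichment(
    table: CountTable,
    meta: SampleMetadata,
    pairs: Sequence[ContrastPair],
    config: AnalysisConfig | None = None,
    *,
    adjust: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Substrate-responder detection over a set of library pairs.

    Returns ``(records, calls)``: per-pair enrichment records and the
    per-phylotype responder calls aggregated with the >= min_libraries rule.
    """
    config = config or AnalysisConfig()
    if len(pairs) < config.min_libraries:
        raise ValidationError(
            f"{len(pairs)} library pairs cannot satisfy min_libraries="
            f"{config.min_libraries}"
        )
    records = _enrichment_records(table, meta, pairs, config, adjust=adjust)
    return records, _aggregate_calls(records, config)


def test_inhibition(
    table: CountTable,
    meta: SampleMetadata,
    pairs: Sequence[ContrastPair],
    config: AnalysisConfig | None = None,
    *,
    adjust: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Molybdate-inhibition test: same machinery as enrichment, contrasting
    uninhibited substrate libraries against molybdate-inhibited ones.

    Returns ``(records, srm)`` where ``srm`` is a boolean Series per
    phylotype: enriched in >= min_libraries of the pairs.
    """
    records, calls = test_enrichment(table, meta, pairs, config, adjust=adjust)
    srm = calls.set_index("phylotype_id")["responsive"].rename("srm")
    return records, srm


def classify_guilds(
    spirulina_responsive: pd.Series,
    acetate_responsive: pd.Series,
    srm: pd.Series,
) -> pd.DataFrame:
    """Map the three per-phylotype booleans onto functional guilds.

    Decision table (total on all 8 combinations):

    ==========  =======  ====  ======================
    spirulina   acetate  srm   guild
    ==========  =======  ====  ======================
    T           F        F     hydrolyser_fermenter
    any         T        T     acetate_utilizing_srm
    F           F        T     srm_other_donor
    T           T        F     vfa_utilizer_non_srm
    F           T        F     vfa_utilizer_non_srm
    T           F        T     unclassified
    F           F        F     unclassified
    ==========  =======  ====  ======================
    """
    idx = spirulina_responsive.index
    if not (idx.equals(acetate_responsive.index) and idx.equals(srm.index)):
        raise ValidationError("guild inputs must share one phylotype index")
    s = spirulina_responsive.astype(bool).to_numpy()
    a = acetate_responsive.astype(bool).to_numpy()
    m = srm.astype(bool).to_numpy()
    guild = np.full(len(idx), "unclassified", dtype=object)
    guild[s & ~a & ~m] = "hydrolyser_fermenter"
    guild[a & m] = "acetate_utilizing_srm"
    guild[m & ~s & ~a] = "srm_other_donor"
    guild[(a | s) & ~m & ~(s & ~a)] = "vfa_utilizer_non_srm"
    return pd.DataFrame(
        {
            "phylotype_id": idx,
            "spirulina_responsive": s,
            "acetate_responsive": a,
            "srm": m,
            "guild": guild,
        }
    )


def compare_rates(
    rates_treatment: Sequence[float], rates_control: Sequence[float]
) -> TestResult:
    """Wilcoxon rank-sum comparison of process rates (e.g. sulfate reduction
    rates in amended vs unamended incubations); two-sided."""
    return wilcoxon_rank_sum(rates_treatment, rates_control, "two_sided")


# ---------------------------------------------------------------------------
# model / results surface


class ResponderModel:
    """Responder-detection model over a count table and its incubation design.

    Parameters
    ----------
    counts, metadata
        The phylotype x sample read counts and the per-sample design table.
    config
        Shared statistical knobs (alpha, min_libraries, ...).
    substrate_contrasts, inhibition_contrasts
        Explicit library pairings.  When omitted they are built from the
        metadata by matching on (day, dose, molecule) at the two latest
        sampling days, high dose.
    """

    def __init__(
        self,
        counts: CountTable,
        metadata: SampleMetadata,
        config: AnalysisConfig | None = None,
        *,
        substrate_contrasts: dict[str, Sequence[ContrastPair]] | None = None,
        inhibition_contrasts: Sequence[ContrastPair] | None = None,
        dose: str = "HD",
        days: Sequence[int] | None = None,
    ) -> None:
        metadata.validate_against(counts)
        self.counts = counts
        self.metadata = metadata
        self.config = config or AnalysisConfig()
        if substrate_contrasts is None:
            substrate_contrasts = {}
            for substrate in ("spirulina", "acetate"):
                if not metadata.select(substrate=substrate).empty:
                    substrate_contrasts[substrate] = build_substrate_contrasts(
                        metadata, substrate, dose=dose, days=days
                    )
        self.substrate_contrasts = {k: list(v) for k, v in substrate_contrasts.items()}
        if inhibition_contrasts is None:
            try:
                inhibition_contrasts = build_inhibition_contrasts(
                    metadata, dose=dose, days=days
                )
            except ValidationError:
                inhibition_contrasts = []
        self.inhibition_contrasts = list(inhibition_contrasts)

    @classmethod
    def from_files(
        cls, counts_path, metadata_path, config: AnalysisConfig | None = None, **kwargs
    ) -> "ResponderModel":
        from .io import read_count_table, read_sample_metadata

        return cls(
            read_count_table(counts_path),
            read_sample_metadata(metadata_path),
            config,
            **kwargs,
        )

    def fit(self) -> "ResponderResults":
        records = {}
        calls = {}
        for substrate, pairs in self.substrate_contrasts.items():
            records[substrate], calls[substrate] = test_enrichment(
                self.counts, self.metadata, pairs, self.config
            )
        if self.inhibition_contrasts:
            inhibition_records, srm = test_inhibition(
                self.counts, self.metadata, self.inhibition_contrasts, self.config
            )
        else:
            inhibition_records = pd.DataFrame()
            srm = pd.Series(False, index=self.counts.counts.index, name="srm")
        index = pd.Index(self.counts.phylotype_ids, name="phylotype_id")

        def _flag(substrate: str) -> pd.Series:
            if substrate in calls:
                return (
                    calls[substrate]
                    .set_index("phylotype_id")["responsive"]
                    .reindex(index, fill_value=False)
                )
            return pd.Series(False, index=index)

        guilds = classify_guilds(
            _flag("spirulina"), _flag("acetate"), srm.reindex(index, fill_value=False)
        )
        return ResponderResults(
            model=self,
            enrichment_records=records,
            responder_calls=calls,
            inhibition_records=inhibition_records,
            srm=srm.reindex(index, fill_value=False),
            guilds=guilds,
        )


@dataclass
class ResponderResults:
    """Fitted responder-detection results.

    Attributes
    ----------
    enrichment_records
        Per-substrate DataFrames of phylotype x library-pair tests.
    responder_calls
        Per-substrate DataFrames of aggregated per-phylotype calls.
    srm
        Boolean Series: molybdate-inhibited (putative sulfate reducer).
    guilds
        Functional-guild assignment per phylotype.
    """

    model: ResponderModel
    enrichment_records: dict[str, pd.DataFrame]
    responder_calls: dict[str, pd.DataFrame]
    inhibition_records: pd.DataFrame
    srm: pd.Series
    guilds: pd.DataFrame

    def responsive_phylotypes(self, substrate: str) -> list[str]:
        calls = self.responder_calls.get(substrate)
        if calls is None:
            return []
        return calls.loc[calls["responsive"], "phylotype_id"].tolist()

    def srm_phylotypes(self) -> list[str]:
        return self.srm.index[self.srm].tolist()

    def to_report(self) -> dict:
        """JSON-ready nested report of all calls and guild assignments."""
        report = {
            "config": {
                "alpha": self.model.config.alpha,
                "min_libraries": self.model.config.min_libraries,
            },
            "substrates": {},
            "srm_phylotypes": self.srm_phylotypes(),
            "guilds": self.guilds[self.guilds["guild"] != "unclassified"].to_dict(
                orient="records"
            ),
        }
        for substrate, calls in self.responder_calls.items():
            hits = calls[calls["responsive"]]
            report["substrates"][substrate] = hits.to_dict(orient="records")
        return report

    def summary(self) -> str:
        lines = ["Responder detection summary", "=" * 27]
        cfg = self.model.config
        lines.append(
            f"alpha={cfg.alpha}  min_libraries={cfg.min_libraries}  "
            f"phylotypes={self.model.counts.shape[0]}"
        )
        for substrate, calls in self.responder_calls.items():
            hits = calls[calls["responsive"]]
            n_growth = int((hits["response_mode"] == "growth").sum())
            n_activity = int((hits["response_mode"] == "activity").sum())
            lines.append(
                f"{substrate:>10}: {len(hits)} responsive "
                f"({n_growth} growth, {n_activity} activity-only) "
                f"over {len(self.model.substrate_contrasts[substrate])} library pairs"
            )
        lines.append(
            f"       SRM: {int(self.srm.sum())} molybdate-inhibited phylotypes "
            f"over {len(self.model.inhibition_contrasts)} library pairs"
        )
        counts = self.guilds["guild"].value_counts()
        for guild in GUILDS:
            if guild != "unclassified" and counts.get(guild, 0):
                lines.append(f"{counts[guild]:>10} x {guild}")
        return "\n".join(lines)
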