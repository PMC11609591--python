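"""End-to-end survey orchestration: filter -> fold -> C_L -> aggregate -> compare.

`run_survey` drives the full analysis over a set of annotated mRNA records;
`run_random_control` reproduces the uniform-random-sequence null model;
`compare_mfe_suboptimal` checks that the contour length is stable across the
lowest-free-energy suboptimal structures of the same molecule.

Every eligible record appears in the report, either measured or skipped with
a logged reason — records are never silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import folding, sequence_io, stats, synthetic_data
from .errors import DomainError, EndloopError
from .exterior_loop import (
    DEFAULT_LINK_NM,
    LinkConvention,
    exterior_summary,
)
from .folding import FoldConfig, SecondaryStructure
from .sequence_io import FilterCriteria, MRNARecord
from .stats import GaussianFitResult, LinearFitResult, WelchResult
from .synthetic_data import RandomSeqSpec

logger = logging.getLogger("endloop")

__all__ = [
    "SurveyConfig",
    "SurveyReport",
    "GroupComparison",
    "RandomControlResult",
    "run_survey",
    "run_random_control",
    "compare_mfe_suboptimal",
]

PER_MOLECULE_COLUMNS = [
    "id",
    "species_code",
    "clade",
    "gene_class",
    "length_nt",
    "gc_percent",
    "utr3_nt",
    "ext_unpaired",
    "top_helices",
    "link_count",
    "contour_length_nm",
]


@dataclass(frozen=True)
class SurveyConfig:
    """Knobs for the end-to-end survey."""

    fold: FoldConfig = FoldConfig()
    criteria: FilterCriteria = FilterCriteria()
    convention: LinkConvention = LinkConvention.CLOSING_PAIR
    d: float = DEFAULT_LINK_NM
    bin_width: float = 2.0
    trim_polya: bool = True
    #: gene_class pairs to contrast with Welch's test, e.g. (("homologous",
    #: "heterologous"),); species-level pairs are given as 2-tuples of codes
    #: prefixed "species:".
    comparisons: tuple[tuple[str, str], ...] = ()
    #: presentation order of species codes in the per-species table
    species_order: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupComparison:
    label: str
    n_x: int
    n_y: int
    result: WelchResult | None
    note: str = ""


@dataclass(frozen=True)
class RandomControlResult:
    fit: GaussianFitResult
    upper_bound: float  # nm
    values: np.ndarray  # per-sequence C_L, nm
    seed: int


@dataclass
class SurveyReport:
    per_molecule: pd.DataFrame
    per_species: pd.DataFrame
    native_fit: GaussianFitResult | None
    comparisons: list[GroupComparison]
    correlations: dict[str, LinearFitResult]
    skipped: pd.DataFrame  # id, reason
    engine: str

    def to_files(self, outdir: str | Path) -> None:
        """per_molecule.tsv, per_species.tsv, fits.json, comparisons.json."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_molecule.to_csv(out / "per_molecule.tsv", sep="\t", index=False)
        self.per_species.to_csv(out / "per_species.tsv", sep="\t", index=False)
        fits: dict = {"engine": self.engine}
        if self.native_fit is not None:
            f = self.native_fit
            fits["native"] = {
                "center_nm": f.center,
                "center_sd_nm": f.center_sd,
                "width_w_nm": f.width_w,
                "width_sd_nm": f.width_sd,
                "bin_width_nm": f.bin_width,
                "n": f.n_points,
                "upper_bound_95_nm": stats.upper_bound_95(f),
            }
        fits["correlations"] = {
            label: {
                "intercept_nm": lf.intercept,
                "intercept_sd_nm": lf.intercept_sd,
                "slope": lf.slope,
                "slope_sd": lf.slope_sd,
                "pearson_r": lf.pearson_r,
                "p_value": lf.p_value,
                "n": lf.n,
            }
            for label, lf in self.correlations.items()
        }
        (out / "fits.json").write_text(json.dumps(fits, indent=2) + "\n")
        comp = [
            {
                "label": c.label,
                "n_x": c.n_x,
                "n_y": c.n_y,
                "t": None if c.result is None else c.result.t_statistic,
                "dof": None if c.result is None else c.result.dof,
                "p_value": None if c.result is None else c.result.p_value,
                "note": c.note,
            }
            for c in self.comparisons
        ]
        (out / "comparisons.json").write_text(json.dumps(comp, indent=2) + "\n")
        if len(self.skipped):
            self.skipped.to_csv(out / "skipped.tsv", sep="\t", index=False)


def _measure_record(
    record: MRNARecord, config: SurveyConfig
) -> tuple[dict, SecondaryStructure]:
    seq = record.sequence
    if config.trim_polya:
        seq = sequence_io.trim_polya_tail(seq, config.criteria.min_polya_run)
    structure = folding.fold_mfe(seq, config.fold)
    summary = exterior_summary(structure, convention=config.convention, d=config.d)
    row = {
        "id": record.id,
        "species_code": record.species_code,
        "clade": record.clade.value,
        "gene_class": record.gene_class.value,
        "length_nt": len(record),
        "gc_percent": sequence_io.gc_content(record.sequence),
        "utr3_nt": sequence_io.utr3_length(record),
        "ext_unpaired": summary.ext_unpaired,
        "top_helices": summary.top_helices,
        "link_count": summary.link_count,
        "contour_length_nm": summary.contour_length,
    }
    return row, structure


def _welch_or_note(x: np.ndarray, y: np.ndarray, label: str) -> GroupComparison:
    try:
        res = stats.welch_test(x, y)
        return GroupComparison(label=label, n_x=len(x), n_y=len(y), result=res)
    except DomainError as exc:
        return GroupComparison(
            label=label, n_x=len(x), n_y=len(y), result=None, note=str(exc)
        )


def run_survey(
    records: Sequence[MRNARecord], config: SurveyConfig = SurveyConfig()
) -> SurveyReport:
    """Fold every eligible record and build the survey report.

    Records failing the eligibility criteria are reported as skipped with
    their failure codes; folding failures are likewise skipped with the
    engine diagnostic, never silently dropped.
    """
    if not records:
        raise DomainError("no records supplied")
    rows: list[dict] = []
    skipped: list[dict] = []
    engine = "none"
    for record in records:
        result = sequence_io.check_eligibility(record, config.criteria)
        if not result.passed:
            reason = "ineligible: " + ";".join(c.value for c in result.failures)
            skipped.append({"id": record.id, "reason": reason})
            logger.info("skipping %s (%s)", record.id, reason)
            continue
        try:
            row, structure = _measure_record(record, config)
        except EndloopError as exc:
            skipped.append({"id": record.id, "reason": f"folding failed: {exc}"})
            logger.warning("folding failed for %s: %s", record.id, exc)
            continue
        engine = structure.engine
        rows.append(row)
    per_molecule = pd.DataFrame(rows, columns=PER_MOLECULE_COLUMNS)
    per_species = _aggregate_species(per_molecule, config.species_order)

    native_fit: GaussianFitResult | None = None
    if len(per_molecule) >= 10:
        try:
            native_fit = stats.fit_gaussian(
                per_molecule["contour_length_nm"], config.bin_width
            )
        except EndloopError as exc:
            logger.warning("pooled Gaussian fit unavailable: %s", exc)

    comparisons = _run_comparisons(per_molecule, config.comparisons)
    correlations = _run_correlations(per_molecule)
    return SurveyReport(
        per_molecule=per_molecule,
        per_species=per_species,
        native_fit=native_fit,
        comparisons=comparisons,
        correlations=correlations,
        skipped=pd.DataFrame(skipped, columns=["id", "reason"]),
        engine=engine,
    )


def _aggregate_species(
    per_molecule: pd.DataFrame, species_order: tuple[str, ...]
) -> pd.DataFrame:
    rows = []
    for code, grp in per_molecule.groupby("species_code", sort=True):
        cl = grp["contour_length_nm"].to_numpy()
        rows.append(
            {
                "species_code": code,
                "clade": grp["clade"].iloc[0],
                "n": len(cl),
                "mean_cl_nm": float(cl.mean()),
                "sem_cl_nm": stats.sem(cl) if len(cl) >= 2 else float("nan"),
            }
        )
    df = pd.DataFrame(
        rows, columns=["species_code", "clade", "n", "mean_cl_nm", "sem_cl_nm"]
    )
    if species_order:
        order = {code: i for i, code in enumerate(species_order)}
        df["_ord"] = df["species_code"].map(lambda c: order.get(c, len(order)))
        df = df.sort_values(["_ord", "species_code"]).drop(columns="_ord")
        df = df.reset_index(drop=True)
    return df


def _run_comparisons(
    per_molecule: pd.DataFrame, pairs: tuple[tuple[str, str], ...]
) -> list[GroupComparison]:
    out: list[GroupComparison] = []
    for g1, g2 in pairs:
        if g1.startswith("species:") and g2.startswith("species:"):
            col = "species_code"
            v1, v2 = g1.split(":", 1)[1], g2.split(":", 1)[1]
        else:
            col, v1, v2 = "gene_class", g1, g2
        x = per_molecule.loc[per_molecule[col] == v1, "contour_length_nm"].to_numpy()
        y = per_molecule.loc[per_molecule[col] == v2, "contour_length_nm"].to_numpy()
        label = f"{v1} vs {v2}"
        if len(x) < 2 or len(y) < 2:
            out.append(
                GroupComparison(
                    label=label,
                    n_x=len(x),
                    n_y=len(y),
                    result=None,
                    note="too few molecules in a group",
                )
            )
            continue
        out.append(_welch_or_note(x, y, label))
    return out


def _run_correlations(per_molecule: pd.DataFrame) -> dict[str, LinearFitResult]:
    out: dict[str, LinearFitResult] = {}
    cl = per_molecule["contour_length_nm"].to_numpy()
    gc = per_molecule["gc_percent"].to_numpy()
    try:
        out["cl_vs_gc"] = stats.pearson_linfit(gc, cl)
    except DomainError as exc:
        logger.info("GC correlation unavailable: %s", exc)
    utr3 = per_molecule["utr3_nt"].to_numpy(dtype=float)
    mask = np.isfinite(utr3)
    if mask.sum() >= 3:
        try:
            out["cl_vs_utr3_length"] = stats.pearson_linfit(utr3[mask], cl[mask])
        except DomainError as exc:
            logger.info("3'UTR-length correlation unavailable: %s", exc)
    return out


def run_random_control(
    spec: RandomSeqSpec, config: SurveyConfig = SurveyConfig()
) -> RandomControlResult:
    """Generate, fold and measure the uniform-random null model.

    Returns the Gaussian fit of the pooled C_L histogram and its one-sided
    95% upper bound.
    """
    if spec.count < 10:
        raise DomainError(
            f"random control needs >= 10 sequences to fit, got {spec.count}"
        )
    sequences = synthetic_data.generate_random_sequences(spec)
    values = np.empty(len(sequences))
    for i, seq in enumerate(sequences):
        structure = folding.fold_mfe(seq, config.fold)
        summary = exterior_summary(
            structure, convention=config.convention, d=config.d
        )
        values[i] = summary.contour_length
        logger.debug("random %d/%d: C_L %.2f nm", i + 1, len(sequences), values[i])
    fit = stats.fit_gaussian(values, config.bin_width)
    return RandomControlResult(
        fit=fit,
        upper_bound=stats.upper_bound_95(fit),
        values=values,
        seed=spec.seed,
    )


def compare_mfe_suboptimal(
    sequences: Sequence[str],
    k: int = 5,
    config: SurveyConfig = SurveyConfig(),
) -> tuple[pd.DataFrame, WelchResult]:
    """Contour-length stability across low-energy suboptimal structures.

    For each sequence, folds the MFE structure plus the ``k`` next-lowest
    free-energy suboptimal structures and tabulates C_L(FE_i) / C_L(MFE).
    Returns the ratio table and a two-tailed Welch test comparing the MFE
    C_L values against the pooled suboptimal C_L values.

    Sequences whose MFE contour length is zero have no defined ratio; their
    rows are flagged ``excluded`` and left out of the test.
    """
    if len(sequences) < 2:
        raise DomainError("need >= 2 sequences")
    rows = []
    mfe_cls: list[float] = []
    sub_cls: list[float] = []
    for si, seq in enumerate(sequences):
        structures = folding.fold_suboptimal(seq, k + 1, config.fold)
        cls = [
            exterior_summary(s, convention=config.convention, d=config.d).contour_length
            for s in structures
        ]
        mfe_cl = cls[0]
        excluded = mfe_cl == 0
        if excluded:
            logger.warning("sequence %d: MFE C_L is 0, ratios undefined", si)
        else:
            mfe_cls.append(mfe_cl)
            sub_cls.extend(cls[1:])
        for rank, (s, cl) in enumerate(zip(structures, cls)):
            rows.append(
                {
                    "seq_index": si,
                    "rank": rank,  # 0 = MFE
                    "free_energy": s.free_energy,
                    "contour_length_nm": cl,
                    "ratio_to_mfe": (cl / mfe_cl) if not excluded else float("nan"),
                    "excluded": excluded,
                }
            )
    table = pd.DataFrame(rows)
    welch = stats.welch_test(mfe_cls, sub_cls)
    return table, welch
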