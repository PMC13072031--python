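"""End-to-end analysis: ingest -> ratios -> indices -> stats -> report.

``analyze`` turns a validated :class:`~needlestoich.core_data.StudyDataset`
into an :class:`AnalysisReport` (a pydantic model, hence a published JSON
schema); ``run_analysis`` is the file-to-file wrapper that also writes one
CSV per table. ``run_benchmark`` re-analyses an external deposit mapped to
the canonical schema and emits a side-by-side comparison against the
published reference values of the original field study.

Reports are fully deterministic: re-running on the same inputs and
configuration yields a byte-identical ``report.json`` (no timestamps are
embedded; provenance is a content hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .core_data import (
    CONDITIONS,
    GROUP_CODES,
    SOIL_LAYERS,
    StudyDataset,
    read_study,
)
from .indices import (
    RATIO_NAMES,
    compute_ratios,
    deviation_records,
    homeostatic_index,
    nutrient_stress_index,
    pair_resorption,
    stoichiometric_deviation,
)
from .stats import (
    GatedComparison,
    TestResult,
    correlation_grid,
    gated_group_comparison,
    pca_ratios,
    welch_t_test,
)

log = logging.getLogger("needlestoich")

NEEDLE_VARIABLES = ("c", "n", "p", "c_n", "c_p", "n_p")

#: Published reference values of the original field study, used only by the
#: benchmark comparison table. Needle group means in mg/g (printed to one
#: decimal); SDI values for basal-chlorotic needles vs the 0-20 cm layer;
#: upper bounds reported for the site's soil C:N and C:P.
REFERENCE_NEEDLE_MEANS: dict[str, dict[str, float]] = {
    "AH": {"c": 447.8, "n": 21.9, "p": 8.3},
    "BH": {"c": 481.8, "n": 12.8, "p": 4.3},
    "AC": {"c": 461.4, "n": 24.7, "p": 7.9},
    "BC": {"c": 472.4, "n": 7.2, "p": 1.6},
}
REFERENCE_SDI_BC_TOPSOIL: dict[str, float] = {"c_n": 11.6, "c_p": 16.1, "n_p": 0.73}
REFERENCE_SOIL_RATIO_BOUNDS: dict[str, float] = {"c_n": 7.0, "c_p": 20.0}


def _f(x) -> Optional[float]:
    """JSON-safe float: non-finite -> None."""
    x = float(x)
    return x if np.isfinite(x) else None


class SummaryRow(BaseModel):
    compartment: str
    group: str
    soil_layer: Optional[str] = None
    variable: str
    n: int
    mean: float
    sd: float
    cv: float
    hi: Optional[float] = None
    degenerate: bool = False


class NSIRow(BaseModel):
    sample_id: str
    group: str
    z_cn: float
    z_cp: float
    nsi: float


class ResorptionRow(BaseModel):
    tree_id: str
    condition: str
    nre_n: float
    nre_p: float
    rpi: Optional[float] = None
    rpi_label: str


class TestResultModel(BaseModel):
    test_name: str
    statistic: Optional[float] = None
    df: List[float]
    p_value: Optional[float] = None
    groups: List[str] = []
    note: str = ""

    @classmethod
    def from_result(cls, r: TestResult) -> "TestResultModel":
        return cls(
            test_name=r.test_name,
            statistic=_f(r.statistic),
            df=[d if np.isfinite(d) else -1.0 for d in r.df],
            p_value=_f(r.p_value),
            groups=list(r.groups),
            note=r.note,
        )


class PairwiseRow(BaseModel):
    group1: str
    group2: str
    statistic: float
    p_value: float


class GatedComparisonModel(BaseModel):
    variable: str
    levene: TestResultModel
    route: str
    omnibus: TestResultModel
    pairwise: List[PairwiseRow]
    letters: Dict[str, str]

    @classmethod
    def from_comparison(cls, variable: str, g: GatedComparison) -> "GatedComparisonModel":
        rows = [] if g.pairwise is None else [
            PairwiseRow(**r) for r in g.pairwise.table.to_dict("records")
        ]
        return cls(
            variable=variable,
            levene=TestResultModel.from_result(g.levene),
            route=g.route,
            omnibus=TestResultModel.from_result(g.omnibus),
            pairwise=rows,
            letters=g.letters or {},
        )


class SDIRow(BaseModel):
    tree_id: str
    condition: str
    position: str
    soil_layer: str
    ratio_name: str
    needle_ratio: float
    soil_ratio: float
    sdi: float


class SDISummaryRow(BaseModel):
    group: str
    soil_layer: str
    ratio_name: str
    sdi_group_mean: float  # mean of per-tree SDI values
    sdi_pooled: float  # SDI of group-mean needle ratio vs layer-mean soil ratio
    n: int


class CorrelationRow(BaseModel):
    needle_group: str
    soil_layer: str
    ratio_name: str
    n: int
    r: Optional[float] = None
    p_value: Optional[float] = None
    p_bh: Optional[float] = None
    flag: str = ""


class PCASection(BaseModel):
    scores: List[Dict[str, float | str]]
    loadings: Dict[str, Dict[str, float]]
    explained_variance_fraction: List[float]


class RunMetadata(BaseModel):
    version: str
    alpha: float
    rpi_coupled_tol: float
    provenance: str
    input_hash: str
    seed: Optional[int] = None


class AnalysisReport(BaseModel):
    """Everything the pipeline computes, in one schema-validated object."""

    model_config = ConfigDict(frozen=True)

    run_metadata: RunMetadata
    group_summaries: List[SummaryRow]
    nsi_table: List[NSIRow]
    resorption_table: List[ResorptionRow]
    resorption_condition_means: Dict[str, Dict[str, Optional[float]]]
    resorption_tests: List[TestResultModel]
    sdi_records: List[SDIRow]
    sdi_summary: List[SDISummaryRow]
    correlations: List[CorrelationRow]
    pca: PCASection
    needle_group_tests: List[GatedComparisonModel]
    soil_layer_tests: List[TestResultModel]

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)


def _input_hash(dataset: StudyDataset, alpha: float, rpi_tol: float) -> str:
    h = hashlib.sha256()
    h.update(dataset.needle_frame().to_csv(index=False).encode())
    h.update(dataset.soil_frame().to_csv(index=False).encode())
    h.update(f"alpha={alpha};rpi_tol={rpi_tol};v={__version__}".encode())
    return h.hexdigest()[:16]


def _needle_values(dataset: StudyDataset) -> dict[str, dict[str, list[float]]]:
    """variable -> group code -> values, over needle samples."""
    out: dict[str, dict[str, list[float]]] = {v: {g: [] for g in GROUP_CODES} for v in NEEDLE_VARIABLES}
    for s in dataset.needles:
        r = compute_ratios(s)
        vals = {"c": s.c_conc, "n": s.n_conc, "p": s.p_conc,
                "c_n": r.c_n, "c_p": r.c_p, "n_p": r.n_p}
        for v, x in vals.items():
            out[v][s.group].append(x)
    return out


def analyze(
    dataset: StudyDataset,
    alpha: float = 0.05,
    rpi_coupled_tol: float = 0.1,
    seed: Optional[int] = None,
) -> AnalysisReport:
    """Run every analysis stage in fixed order on a validated dataset."""
    log.info("stage=ingest needles=%d soils=%d", len(dataset.needles), len(dataset.soils))

    # --- group summaries (concentrations + ratios, needles then soils) ---
    summaries: list[SummaryRow] = []
    needle_vals = _needle_values(dataset)
    for v in NEEDLE_VARIABLES:
        for g in GROUP_CODES:
            vals = needle_vals[v][g]
            if len(vals) < 2:
                continue
            s = homeostatic_index(vals, group=g, variable=v)
            summaries.append(SummaryRow(
                compartment="needle", group=g, variable=v, n=s.n, mean=s.mean,
                sd=s.sd, cv=s.cv, hi=_f(s.hi), degenerate=s.degenerate,
            ))
    soil_vals: dict[tuple[str, str, str], list[float]] = {}
    for smp in dataset.soils:
        r = compute_ratios(smp)
        vals = {"c": smp.c_conc, "n": smp.n_conc, "p": smp.p_conc,
                "c_n": r.c_n, "c_p": r.c_p, "n_p": r.n_p}
        for v, x in vals.items():
            soil_vals.setdefault((smp.condition, smp.soil_layer, v), []).append(x)
    for condition in CONDITIONS:
        for layer in SOIL_LAYERS:
            for v in NEEDLE_VARIABLES:
                vals = soil_vals.get((condition, layer, v), [])
                if len(vals) < 2:
                    continue
                s = homeostatic_index(vals, group=condition, variable=v)
                summaries.append(SummaryRow(
                    compartment="soil", group=condition, soil_layer=layer, variable=v,
                    n=s.n, mean=s.mean, sd=s.sd, cv=s.cv, hi=_f(s.hi), degenerate=s.degenerate,
                ))
    log.info("stage=summaries rows=%d", len(summaries))

    # --- NSI (standardized across all needle samples of the run) ---
    ratio_pairs = [(s.sample_id, compute_ratios(s)) for s in dataset.needles]
    group_of = {s.sample_id: s.group for s in dataset.needles}
    nsi_rows = [
        NSIRow(sample_id=r.sample_id, group=group_of[r.sample_id],
               z_cn=r.z_cn, z_cp=r.z_cp, nsi=r.nsi)
        for r in nutrient_stress_index(ratio_pairs)
    ]

    # --- resorption (per tree) + condition-level t-tests ---
    resorption = pair_resorption(dataset, coupled_tol=rpi_coupled_tol)
    res_rows = [
        ResorptionRow(tree_id=r.tree_id, condition=r.condition, nre_n=r.nre_n,
                      nre_p=r.nre_p, rpi=r.rpi, rpi_label=r.rpi_label)
        for r in resorption
    ]
    cond_means: dict[str, dict[str, Optional[float]]] = {}
    by_cond: dict[str, list] = {}
    for r in resorption:
        by_cond.setdefault(r.condition, []).append(r)
    for cond, recs in by_cond.items():
        rpis = [r.rpi for r in recs if r.rpi is not None]
        cond_means[cond] = {
            "nre_n": _f(np.mean([r.nre_n for r in recs])),
            "nre_p": _f(np.mean([r.nre_p for r in recs])),
            "rpi": _f(np.mean(rpis)) if rpis else None,
        }
    res_tests: list[TestResultModel] = []
    if set(by_cond) == {"healthy", "chlorotic"}:
        h, c = by_cond["healthy"], by_cond["chlorotic"]
        for var, get in (("nre_n", lambda r: r.nre_n), ("nre_p", lambda r: r.nre_p),
                         ("rpi", lambda r: r.rpi)):
            hx = [get(r) for r in h if get(r) is not None]
            cx = [get(r) for r in c if get(r) is not None]
            if len(hx) >= 2 and len(cx) >= 2:
                t = welch_t_test(hx, cx, labels=("healthy", "chlorotic"))
                res_tests.append(TestResultModel.from_result(
                    TestResult(f"welch_t[{var}]", t.statistic, t.df, t.p_value, t.groups, t.note)))
    log.info("stage=resorption trees=%d", len(res_rows))

    # --- SDI grid: per tree, plus the two group conventions ---
    dev = deviation_records(dataset)
    sdi_rows = [SDIRow(**vars(d)) for d in dev]
    sdi_summary: list[SDISummaryRow] = []
    needle_group_means = {
        (g, v): float(np.mean(needle_vals[v][g])) for v in RATIO_NAMES for g in GROUP_CODES
        if needle_vals[v][g]
    }
    for g in GROUP_CODES:
        condition = "healthy" if g[1] == "H" else "chlorotic"
        position = "apical" if g[0] == "A" else "basal"
        for layer in SOIL_LAYERS:
            for name in RATIO_NAMES:
                per_tree = [d.sdi for d in dev
                            if d.condition == condition and d.position == position
                            and d.soil_layer == layer and d.ratio_name == name]
                soil_mean = soil_vals.get((condition, layer, name))
                if not per_tree or not soil_mean or (g, name) not in needle_group_means:
                    continue
                pooled = stoichiometric_deviation(
                    needle_group_means[(g, name)], float(np.mean(soil_mean)))
                sdi_summary.append(SDISummaryRow(
                    group=g, soil_layer=layer, ratio_name=name,
                    sdi_group_mean=float(np.mean(per_tree)), sdi_pooled=pooled,
                    n=len(per_tree),
                ))
    log.info("stage=sdi records=%d", len(sdi_rows))

    # --- needle-soil Pearson grid ---
    grid = correlation_grid(dataset)
    corr_rows = [
        CorrelationRow(
            needle_group=r.needle_group, soil_layer=r.soil_layer, ratio_name=r.ratio_name,
            n=int(r.n), r=_f(r.r) if pd.notna(r.r) else None,
            p_value=_f(r.p_value) if pd.notna(r.p_value) else None,
            p_bh=_f(r.p_bh) if pd.notna(r.p_bh) else None, flag=r.flag,
        )
        for r in grid.itertuples(index=False)
    ]

    # --- PCA of needle ratios ---
    ratio_table = pd.DataFrame(
        {name: [compute_ratios(s)[name] for s in dataset.needles] for name in RATIO_NAMES},
        index=[s.sample_id for s in dataset.needles],
    )
    pca = pca_ratios(ratio_table)
    pca_section = PCASection(
        scores=[
            {"sample_id": str(idx), **{c: float(row[c]) for c in pca.scores.columns}}
            for idx, row in pca.scores.iterrows()
        ],
        loadings={str(v): {c: float(pca.loadings.loc[v, c]) for c in pca.loadings.columns}
                  for v in pca.loadings.index},
        explained_variance_fraction=[float(x) for x in pca.explained_variance_fraction],
    )
    log.info("stage=pca explained=%s", pca.explained_variance_fraction.round(3).tolist())

    # --- gated group comparisons: needle variables across AH/BH/AC/BC ---
    needle_tests: list[GatedComparisonModel] = []
    for v in NEEDLE_VARIABLES:
        groups = {g: needle_vals[v][g] for g in GROUP_CODES if len(needle_vals[v][g]) >= 2}
        if len(groups) < 2:
            continue
        try:
            cmp_ = gated_group_comparison(groups, alpha=alpha)
        except ValueError as exc:
            log.warning("stage=needle_tests variable=%s skipped: %s", v, exc)
            continue
        needle_tests.append(GatedComparisonModel.from_comparison(v, cmp_))

    # --- soil: healthy vs chlorotic per layer x variable (Welch t) ---
    soil_tests: list[TestResultModel] = []
    for layer in SOIL_LAYERS:
        for v in ("c", "n", "p", "c_n", "c_p", "n_p"):
            h = soil_vals.get(("healthy", layer, v), [])
            c = soil_vals.get(("chlorotic", layer, v), [])
            if len(h) >= 2 and len(c) >= 2:
                t = welch_t_test(h, c, labels=("healthy", "chlorotic"))
                soil_tests.append(TestResultModel.from_result(TestResult(
                    f"welch_t[soil:{layer}:{v}]", t.statistic, t.df, t.p_value, t.groups, t.note)))
    log.info("stage=tests needle=%d soil=%d", len(needle_tests), len(soil_tests))

    return AnalysisReport(
        run_metadata=RunMetadata(
            version=__version__, alpha=alpha, rpi_coupled_tol=rpi_coupled_tol,
            provenance=dataset.provenance,
            input_hash=_input_hash(dataset, alpha, rpi_coupled_tol), seed=seed,
        ),
        group_summaries=summaries,
        nsi_table=nsi_rows,
        resorption_table=res_rows,
        resorption_condition_means=cond_means,
        resorption_tests=res_tests,
        sdi_records=sdi_rows,
        sdi_summary=sdi_summary,
        correlations=corr_rows,
        pca=pca_section,
        needle_group_tests=needle_tests,
        soil_layer_tests=soil_tests,
    )


# ---------------------------------------------------------------------------
# file-level orchestration


def write_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Write report.json and one CSV per table; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path: Path, text: str) -> None:
        path.write_text(text, encoding="utf-8")
        written.append(path)

    try:
        _w(out / "report.json", report.to_json())
        _w(out / "group_summaries.csv",
           pd.DataFrame([r.model_dump() for r in report.group_summaries]).to_csv(index=False))
        _w(out / "nsi.csv",
           pd.DataFrame([r.model_dump() for r in report.nsi_table]).to_csv(index=False))
        _w(out / "resorption.csv",
           pd.DataFrame([r.model_dump() for r in report.resorption_table]).to_csv(index=False))
        _w(out / "sdi_grid.csv",
           pd.DataFrame([r.model_dump() for r in report.sdi_summary]).to_csv(index=False))
        _w(out / "correlations.csv",
           pd.DataFrame([r.model_dump() for r in report.correlations]).to_csv(index=False))
        _w(out / "pca_scores.csv", pd.DataFrame(report.pca.scores).to_csv(index=False))
        letters_rows = [
            {"variable": t.variable, "group": g, "letters": ls}
            for t in report.needle_group_tests for g, ls in t.letters.items()
        ]
        _w(out / "letters.csv", pd.DataFrame(letters_rows).to_csv(index=False))
    except Exception:
        for p in written:  # no partial output set on failure
            p.unlink(missing_ok=True)
        raise
    return written


def run_analysis(
    needles: str | Path,
    soils: str | Path,
    out_dir: str | Path,
    alpha: float = 0.05,
    rpi_coupled_tol: float = 0.1,
    seed: Optional[int] = None,
) -> AnalysisReport:
    """Ingest the two CSVs, analyze, and write the report directory."""
    dataset = read_study(needles, soils)
    report = analyze(dataset, alpha=alpha, rpi_coupled_tol=rpi_coupled_tol, seed=seed)
    write_report(report, out_dir)
    return report


# ---------------------------------------------------------------------------
# benchmark against the published reference values


class BenchmarkRow(BaseModel):
    quantity: str
    computed: Optional[float] = None
    computed_rounded: Optional[float] = None
    reference: Optional[float] = None
    abs_difference: Optional[float] = None
    tolerance: Optional[float] = None
    within_tolerance: Optional[bool] = None
    note: str = ""


def _half_unit(reference: float) -> tuple[float, int]:
    """(half a unit in the last printed digit, number of decimals)."""
    text = f"{reference}"
    decimals = len(text.split(".")[1]) if "." in text else 0
    return 0.5 * 10 ** (-decimals), decimals


def benchmark_comparison(report: AnalysisReport) -> list[BenchmarkRow]:
    """Side-by-side table: recomputed quantities vs the published values.

    Concentration means are compared after rounding to the printed
    precision, with tolerance half a unit in the last printed digit. SDI
    is compared under the group-mean convention first (the pooled value is
    carried in the note). Soil-ratio bounds are reported as pass/fail rows.
    """
    rows: list[BenchmarkRow] = []
    means = {
        (r.group, r.variable): r.mean
        for r in report.group_summaries if r.compartment == "needle"
    }
    for g in GROUP_CODES:
        for v in ("c", "n", "p"):
            ref = REFERENCE_NEEDLE_MEANS[g][v]
            tol, dec = _half_unit(ref)
            computed = means.get((g, v))
            if computed is None:
                rows.append(BenchmarkRow(quantity=f"needle_mean[{g}:{v}]", reference=ref,
                                         tolerance=tol, note="not computed"))
                continue
            rounded = round(computed, dec)
            rows.append(BenchmarkRow(
                quantity=f"needle_mean[{g}:{v}]", computed=computed, computed_rounded=rounded,
                reference=ref, abs_difference=abs(rounded - ref), tolerance=tol,
                within_tolerance=abs(rounded - ref) <= tol,
            ))
    sdi = {(r.group, r.soil_layer, r.ratio_name): r for r in report.sdi_summary}
    for name, ref in REFERENCE_SDI_BC_TOPSOIL.items():
        tol, dec = _half_unit(ref)
        entry = sdi.get(("BC", "0-20", name))
        if entry is None:
            rows.append(BenchmarkRow(quantity=f"sdi[BC:0-20:{name}]", reference=ref,
                                     tolerance=tol, note="not computed"))
            continue
        rounded = round(entry.sdi_group_mean, dec)
        rows.append(BenchmarkRow(
            quantity=f"sdi[BC:0-20:{name}]", computed=entry.sdi_group_mean,
            computed_rounded=rounded, reference=ref, abs_difference=abs(rounded - ref),
            tolerance=tol, within_tolerance=abs(rounded - ref) <= tol,
            note=f"group-mean convention; pooled={entry.sdi_pooled:.3g}",
        ))
    soil_means = {
        (r.group, r.soil_layer, r.variable): r.mean
        for r in report.group_summaries if r.compartment == "soil"
    }
    for name, bound in REFERENCE_SOIL_RATIO_BOUNDS.items():
        vals = [v for (cond, layer, var), v in soil_means.items() if var == name]
        if not vals:
            rows.append(BenchmarkRow(quantity=f"soil_ratio_max[{name}]", reference=bound,
                                     note="not computed"))
            continue
        worst = max(vals)
        rows.append(BenchmarkRow(
            quantity=f"soil_ratio_max[{name}]", computed=worst, reference=bound,
            within_tolerance=worst < bound, note="bound: all layer means below reference",
        ))
    return rows


def run_benchmark(
    deposit_dir: str | Path,
    mapping: str | Path,
    out_dir: str | Path | None = None,
    alpha: float = 0.05,
) -> tuple[AnalysisReport, pd.DataFrame]:
    """Analyze an external deposit and compare against the reference values.

    ``mapping`` is a JSON file describing where the needle and soil tables
    live inside ``deposit_dir`` and how their columns map onto the
    canonical schema::

        {"needles": {"file": "...", "columns": {"sample_id": "ID", ...}},
         "soils":   {"file": "...", "columns": {...}}}

    ``columns`` maps canonical name -> deposit name and may be omitted when
    the deposit already uses canonical names.
    """
    deposit = Path(deposit_dir)
    if not deposit.is_dir() or not any(deposit.iterdir()):
        raise FileNotFoundError(f"deposit directory {deposit} is missing or empty")
    spec = json.loads(Path(mapping).read_text(encoding="utf-8"))
    for key in ("needles", "soils"):
        if key not in spec or "file" not in spec[key]:
            raise ValueError(f"mapping file must provide {key}.file")
    dataset = read_study(
        deposit / spec["needles"]["file"],
        deposit / spec["soils"]["file"],
        columns_needle=spec["needles"].get("columns"),
        columns_soil=spec["soils"].get("columns"),
        provenance=f"deposit:{deposit}",
    )
    report = analyze(dataset, alpha=alpha)
    table = pd.DataFrame([r.model_dump() for r in benchmark_comparison(report)])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out)
        (out / "benchmark_comparison.csv").write_text(table.to_csv(index=False), encoding="utf-8")
    return report, table
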