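"""Stoichiometric ratios and the five nutrient-reallocation indices.

The indices quantify, from C/N/P concentrations alone, how strongly a tree
is remobilizing nutrients from basal (senescing/chlorotic) needles into
apical (green) needles, and how coupled the needle stoichiometry is to the
soil below the tree:

* C:N, C:P, N:P — mass-based elemental ratios per sample.
* HI, the homeostatic index — mean/SD of a ratio within a group; the
  inverse of the coefficient of variation. High HI = tight regulation.
* NSI, the nutrient stress index — per sample, the sum of the z-scores of
  its C:N and C:P ratios computed across *all* needle samples in the run.
  More positive = more jointly N- and P-depleted tissue.
* NRE, nutrient resorption efficiency — 100 x (apical - basal)/apical for
  a nutrient's concentration within one branch; the fraction withdrawn
  from the basal tissue.
* RPI, resorption priority index — NRE_N / NRE_P; above 1 nitrogen is
  withdrawn preferentially, below 1 phosphorus.
* SDI, stoichiometric deviation index — |needle ratio - soil ratio| /
  soil ratio for the matching ratio in a given soil layer of the same
  tree; large SDI = needle stoichiometry decoupled from the soil's.

Group statistics use the sample standard deviation (n-1 denominator)
throughout, consistent with the small-n field design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .core_data import ElementalSample, StudyDataset

RatioName = Literal["c_n", "c_p", "n_p"]
RATIO_NAMES: tuple[str, ...] = ("c_n", "c_p", "n_p")
RATIO_LABELS = {"c_n": "C:N", "c_p": "C:P", "n_p": "N:P"}


class DegenerateReferenceError(ValueError):
    """The standardization reference set has zero spread for a ratio."""


@dataclass(frozen=True)
class StoichRatios:
    """The three mass-based ratios of one sample; n_p * c_n == c_p by construction."""

    c_n: float
    c_p: float
    n_p: float

    def __post_init__(self) -> None:
        if not (self.c_n > 0 and self.c_p > 0 and self.n_p > 0):
            raise ValueError("stoichiometric ratios must be strictly positive")
        if not math.isclose(self.n_p * self.c_n, self.c_p, rel_tol=1e-9):
            raise ValueError("inconsistent ratios: n_p * c_n must equal c_p")

    def __getitem__(self, name: str) -> float:
        if name not in RATIO_NAMES:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptive statistics for one variable, including HI.

    ``hi`` is ``inf`` when the group has zero spread (flagged via
    ``degenerate``), never a crash: a zero-SD group is perfectly
    homeostatic in the limit.
    """

    group: str
    variable: str
    n: int
    mean: float
    sd: float
    cv: float
    hi: float
    degenerate: bool = False


@dataclass(frozen=True)
class NSIRecord:
    sample_id: str
    z_cn: float
    z_cp: float
    nsi: float


@dataclass(frozen=True)
class ResorptionRecord:
    """Per-tree resorption efficiencies and priority, from paired needles."""

    tree_id: str
    condition: str
    n_apical: float
    n_basal: float
    p_apical: float
    p_basal: float
    nre_n: float
    nre_p: float
    rpi: float | None
    rpi_label: str


@dataclass(frozen=True)
class DeviationRecord:
    """Per-tree SDI: one needle position's ratio against one soil layer's."""

    tree_id: str
    condition: str
    position: str
    soil_layer: str
    ratio_name: str
    needle_ratio: float
    soil_ratio: float
    sdi: float


def compute_ratios(sample: ElementalSample) -> StoichRatios:
    """C:N, C:P and N:P mass ratios of one sample."""
    return ratios_from_concentrations(sample.c_conc, sample.n_conc, sample.p_conc)


def ratios_from_concentrations(c: float, n: float, p: float) -> StoichRatios:
    if not (c > 0 and n > 0 and p > 0):
        raise ValueError("concentrations must be strictly positive")
    return StoichRatios(c_n=c / n, c_p=c / p, n_p=n / p)


def homeostatic_index(
    values: Sequence[float] | np.ndarray,
    group: str = "",
    variable: str = "",
) -> GroupSummary:
    """Mean, SD, CV and HI = mean/SD of a group of values.

    Requires n >= 2 and a nonzero mean. SD uses the n-1 denominator. A
    zero-SD group yields cv = 0 and hi = inf with ``degenerate=True``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"homeostatic index needs n >= 2 values, got {x.size}")
    mean = float(np.mean(x))
    if mean == 0.0:
        raise ValueError("homeostatic index undefined for zero mean")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return GroupSummary(group, variable, x.size, mean, 0.0, 0.0, math.inf, degenerate=True)
    cv = sd / mean
    return GroupSummary(group, variable, x.size, mean, sd, cv, mean / sd)


def nutrient_stress_index(
    ratios: Sequence[tuple[str, StoichRatios]],
) -> list[NSIRecord]:
    """NSI = z(C:N) + z(C:P), standardized across the whole reference set.

    The reference set is the full collection passed in — in the study
    design, all needle samples of the run, never recomputed per condition.
    Z-scores use the sample SD (n-1). Over the reference set every z column
    and hence NSI sums to zero.
    """
    if len(ratios) < 2:
        raise ValueError("NSI needs at least 2 samples in the reference set")
    cn = np.array([r.c_n for _, r in ratios], dtype=float)
    cp = np.array([r.c_p for _, r in ratios], dtype=float)
    out: dict[str, np.ndarray] = {}
    for name, col in (("C:N", cn), ("C:P", cp)):
        sd = float(np.std(col, ddof=1))
        if sd == 0.0:
            raise DegenerateReferenceError(f"zero spread of {name} across the reference set")
        out[name] = (col - col.mean()) / sd
    return [
        NSIRecord(sample_id=sid, z_cn=float(z1), z_cp=float(z2), nsi=float(z1 + z2))
        for (sid, _), z1, z2 in zip(ratios, out["C:N"], out["C:P"])
    ]


def resorption_efficiency(c_apical: float, c_basal: float) -> float:
    """NRE in percent: 100 x (apical - basal) / apical.

    Always < 100 for positive concentrations; negative when the element
    accumulates basally (typical for carbon).
    """
    if not c_apical > 0:
        raise ValueError(f"apical concentration must be > 0, got {c_apical}")
    if not c_basal > 0:
        raise ValueError(f"basal concentration must be > 0, got {c_basal}")
    return (c_apical - c_basal) / c_apical * 100.0


def resorption_priority(
    nre_n: float, nre_p: float, coupled_tol: float = 0.1
) -> tuple[float | None, str]:
    """RPI = NRE_N / NRE_P with an interpretation label.

    The label uses a band of half-width ``coupled_tol`` around 1:
    within it "coupled"; within twice it, "coupled/N-leaning" or
    "coupled/P-leaning"; beyond, "N-priority" or "P-priority".
    NRE_P = 0 leaves RPI undefined (None, label "undefined").
    """
    if nre_p == 0.0:
        return None, "undefined"
    rpi = nre_n / nre_p
    delta = rpi - 1.0
    if abs(delta) <= coupled_tol:
        label = "coupled"
    elif abs(delta) <= 2 * coupled_tol:
        label = "coupled/N-leaning" if delta > 0 else "coupled/P-leaning"
    else:
        label = "N-priority" if delta > 0 else "P-priority"
    return rpi, label


def stoichiometric_deviation(needle_ratio: float, soil_ratio: float) -> float:
    """SDI = |needle - soil| / soil; the soil ratio is always the denominator."""
    if not soil_ratio > 0:
        raise ValueError(f"soil ratio must be > 0, got {soil_ratio}")
    return abs(needle_ratio - soil_ratio) / soil_ratio


def pair_resorption(
    dataset: StudyDataset, coupled_tol: float = 0.1
) -> list[ResorptionRecord]:
    """Per-tree NRE_N, NRE_P and RPI from apical/basal needle pairs.

    NRE is computed tree-wise (preserving between-tree variance for the
    condition-level t-test), never from group means. Trees with only an
    apical sample are skipped with a warning; a basal sample without an
    apical partner is an error.
    """
    by_tree: dict[str, dict[str, ElementalSample]] = {}
    for s in dataset.needles:
        by_tree.setdefault(s.tree_id, {})[s.position] = s  # type: ignore[index]
    records = []
    for tree_id in by_tree:  # insertion order = dataset order
        pair = by_tree[tree_id]
        if "basal" in pair and "apical" not in pair:
            raise ValueError(f"tree {tree_id!r}: basal needle sample has no apical partner")
        if "apical" in pair and "basal" not in pair:
            warnings.warn(f"tree {tree_id!r}: apical sample without basal partner, excluded from resorption")
            continue
        a, b = pair["apical"], pair["basal"]
        nre_n = resorption_efficiency(a.n_conc, b.n_conc)
        nre_p = resorption_efficiency(a.p_conc, b.p_conc)
        rpi, label = resorption_priority(nre_n, nre_p, coupled_tol)
        records.append(
            ResorptionRecord(
                tree_id=tree_id,
                condition=a.condition,
                n_apical=a.n_conc,
                n_basal=b.n_conc,
                p_apical=a.p_conc,
                p_basal=b.p_conc,
                nre_n=nre_n,
                nre_p=nre_p,
                rpi=rpi,
                rpi_label=label,
            )
        )
    return records


def deviation_records(dataset: StudyDataset) -> list[DeviationRecord]:
    """The full SDI grid: tree x needle position x soil layer x ratio.

    Pairing is same-tree: the needle ratio of tree i is compared with the
    soil ratio of tree i at each layer, the only design-consistent choice
    given one composite soil profile per tree.
    """
    soil_by_tree: dict[str, dict[str, StoichRatios]] = {}
    for s in dataset.soils:
        soil_by_tree.setdefault(s.tree_id, {})[s.soil_layer] = compute_ratios(s)  # type: ignore[index]
    records = []
    for ndl in dataset.needles:
        nr = compute_ratios(ndl)
        for layer, sr in soil_by_tree.get(ndl.tree_id, {}).items():
            for name in RATIO_NAMES:
                records.append(
                    DeviationRecord(
                        tree_id=ndl.tree_id,
                        condition=ndl.condition,
                        position=ndl.position,  # type: ignore[arg-type]
                        soil_layer=layer,
                        ratio_name=name,
                        needle_ratio=nr[name],
                        soil_ratio=sr[name],
                        sdi=stoichiometric_deviation(nr[name], sr[name]),
                    )
                )
    return records


def group_summaries(
    groups: Iterable[tuple[str, str, Sequence[float]]],
) -> list[GroupSummary]:
    """Convenience: HI/CV summaries for many (group, variable, values) triples."""
    return [homeostatic_index(vals, group=g, variable=v) for g, v, vals in groups]
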