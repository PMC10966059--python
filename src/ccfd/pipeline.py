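"""End-to-end cohort analysis: compensate, binarize, ring, correlate.

``analyze_cohort`` runs the full chain per eye and slab and returns tidy
DataFrames wrapped in a :class:`CohortResult`, which exposes the downstream
statistics (per-ring correlations, slab comparisons, cohort summaries,
two-grader agreement) as methods.  The CLI in :mod:`ccfd.cli` is a thin shell
over this module; library users call it directly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .binarize import (
    DeficitMap,
    PhansalkarParams,
    extract_components,
    fd_percent,
    filter_small_deficits,
    phansalkar_threshold,
)
from .compensation import CompensationParams, compensate_flow
from .exceptions import DegenerateTestError
from .geometry import BinaryMask, EnFaceImage
from .rings import build_rings, ring_fd_profile
from .stats import (
    AgreementResult,
    RingCorrelation,
    cohort_summary,
    icc_two_grader,
    paired_slab_test,
    per_ring_correlation,
    yearly_enlargement_rate,
)
from .synthetic import EyeCase

__all__ = ["AnalysisParams", "CohortResult", "deficit_map_for", "analyze_eye", "analyze_cohort"]

log = logging.getLogger("ccfd")

#: rings within this many widths of the border define the "inner" zone used
#: for agreement summaries (600 um at the default 100 um width)
INNER_RING_COUNT = 6


@dataclass(frozen=True)
class AnalysisParams:
    """All tunables of the analysis stage, with the canonical defaults."""

    compensation: CompensationParams = field(default_factory=CompensationParams)
    phansalkar: PhansalkarParams = field(default_factory=PhansalkarParams)
    min_diameter_um: float = 24.0
    ring_width_um: float = 100.0
    n_rings: int = 12


def deficit_map_for(
    flow: EnFaceImage, structure: EnFaceImage, params: AnalysisParams | None = None
) -> DeficitMap:
    """Compensate, threshold, extract particles and apply the size filter."""
    params = params or AnalysisParams()
    comp = compensate_flow(flow, structure, params.compensation)
    raw = phansalkar_threshold(comp, params.phansalkar)
    return filter_small_deficits(extract_components(raw), params.min_diameter_um)


def analyze_eye(
    eye: EyeCase, params: AnalysisParams | None = None
) -> tuple[list[dict], list[dict], list[dict]]:
    """Analyse one eye; returns (ring_fd rows, whole_fd rows, growth rows)."""
    params = params or AnalysisParams()
    geom = eye.lesion_baseline[0].geometry
    field_mask = BinaryMask(np.ones(geom.shape, dtype=bool), geometry=geom, label="field")

    ring_sets = [
        build_rings(lesion, params.ring_width_um, params.n_rings)
        for lesion in eye.lesion_baseline
    ]

    ring_rows, whole_rows = [], []
    for slab, (flow, structure) in eye.slabs.items():
        dm = deficit_map_for(flow, structure, params)
        whole_rows.append(
            {"eye": eye.eye_id, "slab": slab.name, "fd_pct": fd_percent(dm, field_mask)}
        )
        for g, rings in enumerate(ring_sets):
            profile = ring_fd_profile(dm, rings)
            for k, fd in enumerate(profile, start=1):
                ring_rows.append(
                    {
                        "eye": eye.eye_id,
                        "grader": g + 1,
                        "slab": slab.name,
                        "ring": k,
                        "fd_pct": np.nan if fd is None else fd,
                        "ring_area_mm2": rings.rings[k - 1].area_mm2,
                        "clipped": rings.clipped[k - 1],
                    }
                )

    growth_rows = []
    for g, (b, f) in enumerate(zip(eye.lesion_baseline, eye.lesion_followup)):
        rec = yearly_enlargement_rate(b.area_mm2, f.area_mm2, eye.fu_years)
        growth_rows.append(
            {
                "eye": eye.eye_id,
                "grader": g + 1,
                "ga1_mm2": rec.ga1_mm2,
                "ga2_mm2": rec.ga2_mm2,
                "fu_years": rec.fu_years,
                "yer_mm": rec.yer_mm,
            }
        )
    return ring_rows, whole_rows, growth_rows


@dataclass
class CohortResult:
    """Tidy per-eye tables plus the cohort-level statistics derived from them."""

    ring_fd: pd.DataFrame  # eye, grader, slab, ring, fd_pct, ring_area_mm2, clipped
    whole_fd: pd.DataFrame  # eye, slab, fd_pct
    growth: pd.DataFrame  # eye, grader, ga1_mm2, ga2_mm2, fu_years, yer_mm
    params: AnalysisParams

    @property
    def slab_names(self) -> list[str]:
        return list(self.whole_fd["slab"].unique())

    def yer_series(self, grader: int = 1) -> pd.Series:
        g = self.growth[self.growth["grader"] == grader]
        return g.set_index("eye")["yer_mm"]

    def ring_correlations(self, grader: int = 1, fdr: bool = False) -> pd.DataFrame:
        """Spearman rho/p of FD% vs yER for every (slab, ring)."""
        fd = self.ring_fd[self.ring_fd["grader"] == grader]
        rcs: list[RingCorrelation] = per_ring_correlation(fd, self.yer_series(grader), fdr=fdr)
        return pd.DataFrame(
            [
                {"slab": rc.slab, "ring": rc.ring_index, "rho": rc.rho,
                 "p_value": rc.p_value, "n": rc.n}
                for rc in rcs
            ]
        )

    def slab_tests(self) -> pd.DataFrame:
        """Pairwise Wilcoxon signed-rank tests on whole-image FD% across slabs."""
        wide = self.whole_fd.pivot(index="eye", columns="slab", values="fd_pct")
        rows = []
        names = list(wide.columns)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                try:
                    p = paired_slab_test(wide[a].values, wide[b].values)
                except (DegenerateTestError, ValueError):
                    p = np.nan  # too few pairs or all-tied differences
                rows.append(
                    {"slab_a": a, "slab_b": b, "median_a": wide[a].median(),
                     "median_b": wide[b].median(), "p_value": p}
                )
        return pd.DataFrame(rows)

    def summary(self, grader: int = 1) -> pd.DataFrame:
        """Median/IQR of yER, lesion areas, follow-up, and per-slab FD%."""
        g = self.growth[self.growth["grader"] == grader]
        metrics = {
            "yer_mm": g["yer_mm"].values,
            "ga1_mm2": g["ga1_mm2"].values,
            "ga2_mm2": g["ga2_mm2"].values,
            "fu_years": g["fu_years"].values,
        }
        for slab in self.slab_names:
            metrics[f"fd_pct[{slab}]"] = self.whole_fd.loc[
                self.whole_fd["slab"] == slab, "fd_pct"
            ].values
        return cohort_summary(metrics)

    def agreement(self) -> dict[str, AgreementResult]:
        """Two-grader ICC(2,1) for yER and for inner-ring FD%.

        The FD% agreement subject is an (eye, slab) pair scored by its mean
        FD% over the first :data:`INNER_RING_COUNT` rings with each grader's
        ring grid.  Requires two graders in the tables.
        """
        if set(self.growth["grader"].unique()) != {1, 2}:
            raise ValueError("agreement requires exactly two graders")
        wide_yer = self.growth.pivot(index="eye", columns="grader", values="yer_mm")
        out = {"yer": icc_two_grader(wide_yer[1].values, wide_yer[2].values)}

        inner = self.ring_fd[self.ring_fd["ring"] <= INNER_RING_COUNT]
        mean_fd = (
            inner.groupby(["eye", "slab", "grader"])["fd_pct"].mean().reset_index()
        )
        wide_fd = mean_fd.pivot(index=["eye", "slab"], columns="grader", values="fd_pct").dropna()
        out["fd"] = icc_two_grader(wide_fd[1].values, wide_fd[2].values)
        return out


def analyze_cohort(
    cohort: Iterable[EyeCase],
    params: AnalysisParams | None = None,
) -> CohortResult:
    """Run the full analysis over a cohort of eyes."""
    params = params or AnalysisParams()
    ring_rows, whole_rows, growth_rows = [], [], []
    t0 = time.perf_counter()
    n = 0
    for eye in cohort:
        r, w, g = analyze_eye(eye, params)
        ring_rows += r
        whole_rows += w
        growth_rows += g
        n += 1
    log.info("analyzed %d eyes in %.1f s", n, time.perf_counter() - t0)
    return CohortResult(
        ring_fd=pd.DataFrame(ring_rows),
        whole_fd=pd.DataFrame(whole_rows),
        growth=pd.DataFrame(growth_rows),
        params=params,
    )
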