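"""In-silico pre-clinical trials: factorial runs and statistical analysis.

A trial crosses a cohort of (synthetic or scanned) subjects with belt
models, locking modes and coefficients of adhesion, runs the full pipeline
(placement -> tension -> pressure/geometry equilibrium -> wrench) for each
cell, and applies the comparisons a clinical study would: paired tests for
within-subject factors (belt model, locking), unpaired tests for sex, and
linear regression of mean pressure and bending moment on BMI and the
coefficient of adhesion. Normality is screened per sample with an
Anderson-Darling test at the 5% level; compliant samples use Student's t,
non-compliant ones Wilcoxon (paired) or Mann-Whitney (unpaired). All tests
use alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .belt_placement import ContactModel
from .fabric_mechanics import BeltDesign
from .pressure_engine import (
    MMHG_PER_PA,
    BodyElasticity,
    EquilibriumState,
    equilibrate,
)
from .trunk_surface import TorsoParams, TrunkSurface, synthetic_trunk
from .wrench_analysis import reduce_wrench

__all__ = [
    "ALPHA",
    "Subject",
    "CaseResult",
    "TrialReport",
    "bmi_to_protrusion",
    "make_cohort",
    "run_case",
    "run_cohort",
]

ALPHA = 0.05


def bmi_to_protrusion(bmi: float) -> float:
    """Map BMI to the abdominal protrusion amplitude (m) of the torso generator.

    Linear: 5 mm at BMI 21 (healthy) growing by 5 mm per BMI unit, i.e.
    9 cm of extra anterior radius at BMI 38 (severely obese).
    """
    return max(0.005 + 0.005 * (bmi - 21.0), 0.0)


@dataclass(frozen=True)
class Subject:
    """A (synthetic) trial participant and their torso geometry."""

    subject_id: str
    sex: str
    age: float
    height: float
    weight: float
    bmi: float
    torso: TorsoParams

    def surface(self) -> TrunkSurface:
        surf = synthetic_trunk(self.torso)
        surf.metadata.update(
            subject_id=self.subject_id, sex=self.sex, age=self.age,
            height=self.height, weight=self.weight, bmi=self.bmi,
        )
        return surf


def make_cohort(
    n: int = 15,
    seed: int = 0,
    bmi_range: tuple[float, float] = (21.0, 38.0),
    age_range: tuple[float, float] = (26.0, 56.0),
    height_range: tuple[float, float] = (1.61, 1.82),
    n_theta: int = 360,
    n_z: int = 80,
    noise: float = 0.002,
) -> list[Subject]:
    """Draw a synthetic cohort spanning the study's demographic ranges.

    Sexes alternate (8 women / 7 men at n = 15); BMI, age and height are
    uniform over the given ranges; the abdominal protrusion is the linear
    BMI mapping of :func:`bmi_to_protrusion`, the base cross-section grows
    slightly with BMI, and each torso carries a small seeded smooth noise.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        sex = "F" if i % 2 == 0 else "M"
        bmi = float(rng.uniform(*bmi_range))
        age = float(rng.uniform(*age_range))
        height = float(rng.uniform(*height_range))
        weight = bmi * height**2
        torso = TorsoParams(
            n_theta=n_theta,
            n_z=n_z,
            lateral_radius=0.15 + 0.0012 * (bmi - 21.0),
            ap_radius=0.12 + 0.0010 * (bmi - 21.0),
            protrusion=bmi_to_protrusion(bmi),
            noise=noise,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        subjects.append(
            Subject(
                subject_id=f"S{i + 1:02d}",
                sex=sex,
                age=age,
                height=height,
                weight=weight,
                bmi=bmi,
                torso=torso,
            )
        )
    return subjects


@dataclass
class CaseResult:
    """Outcome indicators of one subject x belt x contact simulation."""

    subject_id: str
    belt: str
    locking: str
    coa: float
    xi: float
    mean_pressure_mmhg: float
    max_pressure_mmhg: float
    bending_moment_nm: float
    max_deflection_mm: float
    converged: bool
    state: Optional[EquilibriumState] = None

    def to_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "belt": self.belt,
            "locking": self.locking,
            "coa": self.coa,
            "xi": self.xi,
            "mean_pressure_mmhg": self.mean_pressure_mmhg,
            "max_pressure_mmhg": self.max_pressure_mmhg,
            "bending_moment_nm": self.bending_moment_nm,
            "max_deflection_mm": self.max_deflection_mm,
            "converged": self.converged,
        }


def run_case(
    surface: TrunkSurface,
    belt: BeltDesign,
    contact: ContactModel,
    elasticity: BodyElasticity,
    nominal_stretch: float = 0.20,
    keep_state: bool = False,
    **equilibrate_opts,
) -> CaseResult:
    """Full pipeline for one case; deterministic given its inputs.

    Mean pressure is the area-weighted mean over the loaded contact cells;
    non-convergence of the equilibrium iteration is recorded, not raised.
    """
    state = equilibrate(
        surface, belt, contact, elasticity, nominal_stretch=nominal_stretch,
        **equilibrate_opts,
    )
    p = state.pressure.p
    area = state.pressure.cell_area
    loaded = p > 0
    if loaded.any():
        mean_p = float(np.average(p[loaded], weights=area[loaded]))
    else:
        mean_p = 0.0
    screw = reduce_wrench(state.pressure, state.surface)
    return CaseResult(
        subject_id=str(surface.metadata.get("subject_id", "anon")),
        belt=belt.name,
        locking=contact.locking,
        coa=contact.adhesion,
        xi=contact.xi,
        mean_pressure_mmhg=mean_p * MMHG_PER_PA,
        max_pressure_mmhg=float(p.max()) * MMHG_PER_PA,
        bending_moment_nm=screw.M_t,
        max_deflection_mm=float(state.deflection.u_z.max()) * 1e3,
        converged=state.converged,
        state=state if keep_state else None,
    )


def _difference_test(x: np.ndarray, y: np.ndarray, paired: bool) -> dict:
    """Paired/unpaired two-sample test with Anderson-Darling normality screen."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        d = x - y
        if np.allclose(d, 0):
            return {"test": "wilcoxon", "statistic": 0.0, "p_value": 1.0,
                    "normal": False, "n": int(d.size)}
        normal = _anderson_normal(d)
        if normal:
            stat, p = stats.ttest_rel(x, y)
            name = "paired t"
        else:
            stat, p = stats.wilcoxon(x, y)
            name = "wilcoxon"
        n = d.size
    else:
        normal = _anderson_normal(x) and _anderson_normal(y)
        if normal:
            stat, p = stats.ttest_ind(x, y)
            name = "t"
        else:
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            name = "mann-whitney"
        n = x.size + y.size
    return {"test": name, "statistic": float(stat), "p_value": float(p),
            "normal": bool(normal), "n": int(n)}


def _anderson_normal(x: np.ndarray) -> bool:
    """True when an Anderson-Darling test does not reject normality at 5%."""
    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.ptp(x) == 0:
        return False
    try:  # SciPy >= 1.17 requires an explicit p-value method
        res = stats.anderson(x, dist="norm", method="interpolate")
        return bool(res.pvalue > ALPHA)
    except TypeError:
        res = stats.anderson(x, dist="norm")
        crit_5 = res.critical_values[list(res.significance_level).index(5.0)]
        return bool(res.statistic < crit_5)


@dataclass
class TrialReport:
    """Case table plus test results of one factorial in-silico trial."""

    cases: pd.DataFrame
    tests: dict
    alpha: float = ALPHA


def _regressions(cases: pd.DataFrame) -> dict:
    """OLS of each outcome on BMI and CoA with slope t-tests."""
    out = {}
    for outcome in ("mean_pressure_mmhg", "bending_moment_nm"):
        sub = cases.dropna(subset=[outcome, "bmi"])
        exog_cols = ["bmi"]
        if sub["coa"].nunique() > 1:
            exog_cols.append("coa")
        X = sm.add_constant(sub[exog_cols].to_numpy(dtype=float))
        model = sm.OLS(sub[outcome].to_numpy(dtype=float), X).fit()
        res = {}
        for name, slope, pval in zip(exog_cols, model.params[1:], model.pvalues[1:]):
            res[name] = {
                "slope": float(slope),
                "p_value": float(pval),
                "significant": bool(pval < ALPHA),
            }
        out[outcome] = res
    return out


def run_cohort(
    subjects: Sequence[Subject],
    belts: Sequence[BeltDesign],
    lockings: Sequence[str] = ("frictionless",),
    coas: Sequence[float] = (0.3,),
    xi: float = 1.0,
    elasticity: Optional[BodyElasticity] = None,
    nominal_stretch: float = 0.20,
    **equilibrate_opts,
) -> TrialReport:
    """Run the complete factorial trial and its statistical analysis.

    The design is fully crossed (subjects x belts x lockings x CoAs);
    paired comparisons pair on subject id across matched cells. Results
    are bit-reproducible for fixed subjects and invariant to subject order.
    """
    if len(subjects) < 2:
        raise ValueError("at least 2 subjects are required for the trial statistics")
    if elasticity is None:
        elasticity = BodyElasticity()

    subjects = sorted(subjects, key=lambda s: s.subject_id)
    rows = []
    for subj in subjects:
        surf = subj.surface()
        for belt, locking, coa in product(belts, lockings, coas):
            contact = ContactModel(adhesion=coa, xi=xi, locking=locking)
            case = run_case(
                surf, belt, contact, elasticity,
                nominal_stretch=nominal_stretch, **equilibrate_opts,
            )
            row = case.to_row()
            row.update(sex=subj.sex, bmi=subj.bmi, age=subj.age)
            rows.append(row)
    cases = pd.DataFrame(rows).sort_values(
        ["subject_id", "belt", "locking", "coa"], ignore_index=True
    )

    tests: dict = {}
    key_cols = ["subject_id", "locking", "coa"]
    if len(belts) >= 2:
        tests["belt_effect"] = _paired_factor_tests(
            cases, factor="belt",
            levels=[belts[0].name, belts[1].name],
            pair_on=key_cols,
        )
    if len(lockings) >= 2:
        tests["locking_effect"] = _paired_factor_tests(
            cases, factor="locking", levels=list(lockings)[:2],
            pair_on=["subject_id", "belt", "coa"],
        )
    sexes = cases["sex"].unique()
    if len(sexes) >= 2:
        per_subj = cases.groupby(["subject_id", "sex"], as_index=False).mean(
            numeric_only=True
        )
        tests["sex_effect"] = {
            outcome: _difference_test(
                per_subj.loc[per_subj["sex"] == sexes[0], outcome].to_numpy(),
                per_subj.loc[per_subj["sex"] == sexes[1], outcome].to_numpy(),
                paired=False,
            )
            for outcome in ("mean_pressure_mmhg", "bending_moment_nm")
        }
    tests["regression"] = _regressions(cases)
    return TrialReport(cases=cases, tests=tests)


def _paired_factor_tests(cases: pd.DataFrame, factor: str, levels: list,
                         pair_on: list) -> dict:
    """Paired tests between two levels of a within-subject factor."""
    a = cases[cases[factor] == levels[0]].set_index(pair_on).sort_index()
    b = cases[cases[factor] == levels[1]].set_index(pair_on).sort_index()
    missing = a.index.symmetric_difference(b.index)
    if len(missing):
        raise ValueError(
            f"incomplete pairing for factor {factor!r}: missing cells {list(missing)[:5]}"
        )
    out = {}
    for outcome in ("mean_pressure_mmhg", "bending_moment_nm"):
        out[outcome] = _difference_test(
            a[outcome].to_numpy(), b[outcome].to_numpy(), paired=True
        )
    return out
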