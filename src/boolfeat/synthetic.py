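"""Synthetic data generators.

Two families of fixtures make every stage of the pipeline testable without
any data download:

* **Planted-rule datasets** — correlated Gaussian features with labels driven
  by a known Boolean representation, either deterministically (with optional
  label-flip noise) or through a logistic link over several weighted Boolean
  terms.  Recovery of the planted structure is the main end-to-end oracle.

* **EHR-like cohorts** — per-subject latent longitudinal trajectories (years
  of encounters, antihypertensive medication-class counts, blood pressures,
  labs, diagnosis codes) summarized into subject-level columns in the style of
  a phenotyping feature table ("# enc 3+ meds, sum", "SBP, mean",
  "Calcium, max", ...).  Labels come from an expert-style apparent
  treatment-resistant hypertension (aTRH) heuristic applied to the *latent*
  trajectories, so the summarized features relate to the outcome only
  statistically — emulating the gap between chart review and extracted
  features.  Distributional parameters are calibrated to qualitative realism
  only (about 10% outcome prevalence, plausible vital/lab ranges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import expressions as ex
from .datasets import Dataset
from .exceptions import DegenerateDataError
from .logistic import sigmoid


# ---------------------------------------------------------------------------
# planted-rule datasets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Recipe for a planted-rule classification dataset."""

    n: int
    d: int
    rule: ex.Representation
    label_noise: float = 0.0
    target_prevalence: float | None = None
    correlated_block_spec: tuple[tuple[int, float], ...] = ()
    coefficients: tuple[float, ...] | None = None
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.target_prevalence is not None and not (0 < self.target_prevalence < 1):
            raise ValueError("target_prevalence must lie in (0, 1)")
        for size, rho in self.correlated_block_spec:
            if not (-1 < rho < 1):
                raise ValueError("block correlations must lie in (-1, 1)")
        if self.coefficients is not None and len(self.coefficients) != self.rule.p:
            raise ValueError("coefficients must match the rule's dimensionality")
        max_idx = max(
            n.feature_index
            for t in self.rule.trees
            for n in t.walk()
            if n.feature_index is not None
        )
        if max_idx >= self.d:
            raise ValueError("rule references a feature index >= d")


def _gaussian_features(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    X = rng.standard_normal((spec.n, spec.d))
    col = 0
    for size, rho in spec.correlated_block_spec:
        if col + size > spec.d:
            raise ValueError("correlated blocks exceed d columns")
        cov = np.full((size, size), rho)
        np.fill_diagonal(cov, 1.0)
        L = np.linalg.cholesky(cov)
        X[:, col : col + size] = rng.standard_normal((spec.n, size)) @ L.T
        col += size
    return X


def _shift_thresholds(node: ex.Node, s: float) -> ex.Node:
    children = tuple(_shift_thresholds(c, s) for c in node.children)
    if node.kind == ex.GT:
        return ex.Node(ex.GT, node.feature_index, node.threshold + s)
    if node.kind == ex.LT:
        return ex.Node(ex.LT, node.feature_index, node.threshold - s)
    return ex.Node(node.kind, node.feature_index, node.threshold, children)


def make_planted_rule(spec: SyntheticSpec) -> tuple[Dataset, ex.Representation]:
    """Generate features and rule-driven labels; returns (dataset, ground truth).

    Deterministic rules (no coefficients) label by the single tree's 0/1
    output, optionally flipped with probability ``label_noise``; with
    ``coefficients`` set, labels are Bernoulli draws from a logistic link over
    the rule's derived features.  When a target prevalence is requested, the
    rule's thresholds (deterministic case) or intercept (logistic case) are
    shifted to approximate it.
    """
    rng = np.random.default_rng(spec.seed)
    X = _gaussian_features(spec, rng)
    rule = spec.rule

    if spec.coefficients is not None:
        beta = np.asarray(spec.coefficients, dtype=float)
        Phi = ex.evaluate(rule, X)
        b0 = spec.intercept
        if spec.target_prevalence is not None:
            lo, hi = -30.0, 30.0
            for _ in range(80):
                b0 = (lo + hi) / 2
                prev = float(np.mean(sigmoid(Phi @ beta + b0)))
                if prev < spec.target_prevalence:
                    lo = b0
                else:
                    hi = b0
        y = rng.binomial(1, sigmoid(Phi @ beta + b0))
    else:
        if rule.p != 1 or not rule.trees[0].is_boolean:
            raise ValueError(
                "deterministic labeling requires a single Boolean-rooted rule"
            )
        if spec.target_prevalence is not None:
            shifts = np.linspace(-3.0, 3.0, 601)
            prevs = np.array(
                [
                    float(
                        np.mean(
                            ex.evaluate(
                                ex.Representation((
                                    _shift_thresholds(rule.trees[0], s),
                                )),
                                X,
                            )
                        )
                    )
                    for s in shifts
                ]
            )
            best = int(np.argmin(np.abs(prevs - spec.target_prevalence)))
            if abs(prevs[best] - spec.target_prevalence) > 0.05:
                raise DegenerateDataError(
                    f"target prevalence {spec.target_prevalence} unreachable for rule"
                )
            rule = ex.Representation((_shift_thresholds(rule.trees[0], shifts[best]),))
        y = ex.evaluate(rule, X)[:, 0].astype(int)
        if spec.label_noise > 0:
            flips = rng.random(spec.n) < spec.label_noise
            y = np.where(flips, 1 - y, y)

    if np.unique(y).size < 2:
        raise DegenerateDataError("planted rule produced a single-class dataset")
    ds = Dataset(
        X=X,
        y=y,
        feature_names=[f"x{j}" for j in range(spec.d)],
        subject_ids=[f"s{i}" for i in range(spec.n)],
    )
    return ds, rule


# ---------------------------------------------------------------------------
# EHR-like cohorts
# ---------------------------------------------------------------------------

MED_CLASSES = ("thiazide", "acei", "arb", "ccb", "beta_blocker")
LAB_PANEL = ("Potassium", "Calcium", "Sodium", "Creatinine", "Glucose")


@dataclass
class Trajectory:
    """Latent longitudinal record for one synthetic subject."""

    subject_id: str
    years: float
    days: np.ndarray          # encounter days, sorted ascending
    sbp: np.ndarray
    dbp: np.ndarray
    n_meds: np.ndarray        # antihypertensive classes prescribed at each encounter
    exclusion_day: float | None   # heart-failure / CKD flag onset, if any
    labs: dict = field(default_factory=dict)       # lab name -> draws
    med_days: dict = field(default_factory=dict)   # class name -> days prescribed
    htn_dx_per_year: np.ndarray = field(default_factory=lambda: np.zeros(0))
    note_mentions: int = 0
    severity: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.days)
        if not (len(self.sbp) == len(self.dbp) == len(self.n_meds) == n) or n == 0:
            raise ValueError("trajectory arrays must be nonempty and equal length")
        if np.any(np.diff(self.days) < 0):
            raise ValueError("encounter days must be sorted ascending")


def atrh_heuristic_label(trajectories: list[Trajectory]) -> np.ndarray:
    """Expert-style apparent treatment-resistant hypertension rule.

    Positive if (a) at least 2 of 5 consecutive encounters show elevated
    blood pressure (SBP >= 140 or DBP >= 90) while the subject has been on
    >= 3 medication classes continuously for >= 30 days, or (b) the subject
    has been on >= 4 classes continuously for >= 30 days.  Subjects whose
    heart-failure/CKD exclusion flag precedes qualification are negative.
    """
    labels = np.zeros(len(trajectories), dtype=int)
    for i, tr in enumerate(trajectories):
        n = len(tr.days)
        # continuous-run start days for >=3 and >=4 medication classes
        on3_start = np.full(n, np.nan)
        on4_start = np.full(n, np.nan)
        s3 = s4 = np.nan
        for k in range(n):
            if tr.n_meds[k] >= 3:
                s3 = tr.days[k] if np.isnan(s3) else s3
            else:
                s3 = np.nan
            if tr.n_meds[k] >= 4:
                s4 = tr.days[k] if np.isnan(s4) else s4
            else:
                s4 = np.nan
            on3_start[k], on4_start[k] = s3, s4

        qual_day = np.inf
        # branch (b): four or more classes sustained for >= 30 days
        for k in range(n):
            if not np.isnan(on4_start[k]) and tr.days[k] - on4_start[k] >= 30:
                qual_day = min(qual_day, tr.days[k])
                break
        # branch (a): 2 of 5 consecutive elevated encounters on sustained triple therapy
        elevated = (tr.sbp >= 140) | (tr.dbp >= 90)
        eligible = elevated & ~np.isnan(on3_start) & (tr.days - on3_start >= 30)
        for start in range(n):
            window = eligible[start : start + 5]
            if window.sum() >= 2:
                second = np.nonzero(window)[0][1] + start
                qual_day = min(qual_day, tr.days[second])
                break
        if np.isinf(qual_day):
            continue
        if tr.exclusion_day is not None and tr.exclusion_day < qual_day:
            continue
        labels[i] = 1
    return labels


def make_trajectories(n: int, seed: int = 0) -> list[Trajectory]:
    """Simulate latent longitudinal trajectories for ``n`` subjects."""
    rng = np.random.default_rng(seed)
    out: list[Trajectory] = []
    for i in range(n):
        severity = rng.standard_normal()
        years = float(rng.uniform(3, 8))
        n_enc = max(5, rng.poisson(3.5 * years))
        days = np.sort(rng.uniform(0, 365 * years, size=n_enc))

        target_meds = int(np.clip(round(1.1 + 1.3 * severity + rng.normal(0, 0.6)), 0, 5))
        start_meds = max(0, target_meds - 2)
        n_escal = target_meds - start_meds
        escal_at = np.sort(rng.choice(n_enc, size=n_escal, replace=False)) if n_escal else []
        n_meds = np.full(n_enc, start_meds)
        for e in escal_at:
            n_meds[e:] += 1

        sbp = 122 + 10 * severity + rng.normal(0, 11, size=n_enc)
        dbp = 76 + 5 * severity + rng.normal(0, 7, size=n_enc)

        exclusion_day = None
        if rng.random() < 0.10:
            exclusion_day = float(rng.uniform(0, 365 * years))

        sev_pos = max(severity, 0.0)
        thiazide_days = float(rng.uniform(0, 365 * years) * min(1.0, 0.3 + 0.3 * sev_pos))
        labs = {
            "Potassium": rng.normal(4.1 - 0.12 * sev_pos, 0.35, size=8),
            "Calcium": rng.normal(9.4 + 0.0004 * thiazide_days, 0.45, size=8),
            "Sodium": rng.normal(139, 2.5, size=8),
            "Creatinine": rng.normal(1.0 + 0.08 * sev_pos, 0.2, size=8),
            "Glucose": rng.normal(98 + 4 * sev_pos, 14, size=8),
        }
        med_days = {
            "thiazide": thiazide_days,
            "acei": float(rng.uniform(0, 365 * years) * min(1.0, 0.2 + 0.35 * sev_pos)),
            "arb": float(rng.uniform(0, 365 * years) * min(1.0, 0.1 + 0.3 * sev_pos)),
            "ccb": float(rng.uniform(0, 365 * years) * min(1.0, 0.2 + 0.3 * sev_pos)),
            "beta_blocker": float(rng.uniform(0, 365 * years) * min(1.0, 0.2 + 0.25 * sev_pos)),
        }
        n_years = int(np.ceil(years))
        htn_dx = rng.poisson(0.8 + 2.5 * sev_pos, size=n_years)
        notes = int(rng.poisson(4 + 14 * sev_pos))
        out.append(
            Trajectory(
                subject_id=f"s{i}",
                years=years,
                days=days,
                sbp=sbp,
                dbp=dbp,
                n_meds=n_meds,
                exclusion_day=exclusion_day,
                labs=labs,
                med_days=med_days,
                htn_dx_per_year=htn_dx,
                note_mentions=notes,
                severity=severity,
            )
        )
    return out


def _yearly_counts(tr: Trajectory, mask: np.ndarray) -> np.ndarray:
    n_years = int(np.ceil(tr.years))
    year_idx = np.minimum((tr.days / 365).astype(int), n_years - 1)
    return np.bincount(year_idx[mask], minlength=n_years).astype(float)


def summarize_trajectories(
    trajectories: list[Trajectory], d: int = 331, seed: int = 0
) -> tuple[np.ndarray, list[str]]:
    """Summarize latent trajectories into a subject-level feature table.

    Structured columns mirror a phenotyping feature table; if ``d`` exceeds
    their count, weakly outcome-correlated filler lab summaries pad the table
    to ``d`` columns (emulating the long tail of routine labs).
    """
    tiers = [("1", lambda m: m == 1), ("2", lambda m: m == 2), ("3", lambda m: m == 3),
             ("3+", lambda m: m >= 3), ("4+", lambda m: m >= 4)]
    names: list[str] = []
    for tier, _ in tiers:
        names += [f"# enc {tier} meds, sum", f"# enc {tier} meds, median",
                  f"# enc {tier} meds, sd"]
    names += ["SBP, mean", "SBP, max", "DBP, mean", "DBP, max", "# enc elevated BP, sum"]
    for lab in LAB_PANEL:
        names += [f"{lab}, min", f"{lab}, max", f"{lab}, median"]
    names += [f"days on {c}, sum" for c in MED_CLASSES]
    names += ["HTN dx, sum", "HTN dx, median/yr", "HTN note mentions"]

    n_struct = len(names)
    if d < n_struct:
        raise ValueError(f"d must be at least {n_struct}")
    rows = []
    for tr in trajectories:
        row: list[float] = []
        for _, pred in tiers:
            counts = _yearly_counts(tr, pred(tr.n_meds))
            row += [float(counts.sum()), float(np.median(counts)), float(counts.std())]
        elevated = (tr.sbp >= 140) | (tr.dbp >= 90)
        row += [float(tr.sbp.mean()), float(tr.sbp.max()),
                float(tr.dbp.mean()), float(tr.dbp.max()), float(elevated.sum())]
        for lab in LAB_PANEL:
            v = tr.labs[lab]
            row += [float(v.min()), float(v.max()), float(np.median(v))]
        row += [tr.med_days[c] for c in MED_CLASSES]
        row += [float(tr.htn_dx_per_year.sum()),
                float(np.median(tr.htn_dx_per_year)), float(tr.note_mentions)]
        rows.append(row)
    X = np.array(rows)

    n_filler = d - n_struct
    if n_filler:
        rng = np.random.default_rng(seed + 1)
        sev = np.array([tr.severity for tr in trajectories])
        extra = np.empty((len(trajectories), n_filler))
        for j in range(n_filler):
            rho = rng.uniform(0.0, 0.15)
            extra[:, j] = rho * sev + rng.standard_normal(len(trajectories))
            names.append(f"lab panel {j:03d}")
        X = np.hstack([X, extra])
    return X, names


def make_ehr_like(n: int = 1200, d: int = 331, seed: int = 0) -> Dataset:
    """A summarized EHR-like cohort labeled by the aTRH-style heuristic."""
    if n < 100:
        raise ValueError("need at least 100 subjects for a stable cohort")
    trajectories = make_trajectories(n, seed)
    y = atrh_heuristic_label(trajectories)
    X, names = summarize_trajectories(trajectories, d=d, seed=seed)
    return Dataset(
        X=X,
        y=y,
        feature_names=names,
        subject_ids=[tr.subject_id for tr in trajectories],
    )
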