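"""Model/results interface for a preference-elicitation study.

:class:`PreferenceStudy` holds the four data tables of a study — the
participant covariates and the long-format ranking, VAS, and chained
standard-gamble responses — whether simulated or loaded from CSV.  Its
:meth:`~PreferenceStudy.fit` runs the complete analysis: per-option-group
median/IQR summaries, Spearman correlations between instruments, paired
Wilcoxon contrasts (reconstruction vs none, implant vs tissue),
Kruskal-Wallis comparisons across BMI categories, and one univariate
screen + backward-AIC regression per instrument and option group.  The
returned :class:`PreferenceStudyResults` carries the tables, the twelve
regression models, and a printable summary.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .simulate import SimulatedStudy, simulate_study
from .states import RECON_QUALITIES, build_deck
from .stats import (
    RegressionModel,
    TestResult,
    backward_aic,
    bmi_compare,
    paired_compare,
    rank_utility_correlation,
    univariate_screen,
)

MEASURES = ("rank", "vas", "vas_death", "utility")
GROUPS = ("any", "implant", "tissue", "none")

#: states contributing to each (group, quality) summary cell
def _cell_states(group: str, quality: str) -> list[str]:
    if group == "none":
        return ["none"]
    modalities = ("implant", "tissue") if group == "any" else (group,)
    qualities = RECON_QUALITIES if quality == "pooled" else (quality,)
    return [f"{m}_{q}" for m in modalities for q in qualities]


def _rows() -> list[tuple[str, str]]:
    rows = []
    for group in ("any", "implant", "tissue"):
        rows.append((group, "pooled"))
        rows += [(group, q) for q in RECON_QUALITIES]
    rows.append(("none", "pooled"))
    return rows


def _wide(table: pd.DataFrame, value: str) -> pd.DataFrame:
    sub = table[table["state_id"] != "death"]
    return sub.pivot_table(index="participant_id", columns="state_id",
                           values=value, aggfunc="first", observed=True)


def group_scores(
    wide: pd.DataFrame, group: str, quality: str = "pooled", aggregate: str = "mean"
) -> pd.Series:
    """Per-participant option-group score: mean (or median) over the cell's states.

    Participants missing any state of the cell get NaN (listwise per column).
    """
    cols = [c for c in _cell_states(group, quality) if c in wide.columns]
    want = _cell_states(group, quality)
    if set(cols) != set(want):
        return pd.Series(np.nan, index=wide.index)
    block = wide[want]
    scores = block.median(axis=1) if aggregate == "median" else block.mean(axis=1)
    return scores.where(block.notna().all(axis=1))


def summarize(
    elicitation: Optional[pd.DataFrame] = None,
    rankings: Optional[pd.DataFrame] = None,
    ratings: Optional[pd.DataFrame] = None,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Median/IQR summary table over option groups and qualities.

    Rows are (option group, quality) cells — 'any', 'implant', 'tissue'
    each pooled and split by quality, plus the no-reconstruction row.
    Columns give median, IQR, quartiles and n for the no-death ranking,
    the VAS without and with death, and the chained-gamble utility.
    Empty cells are reported as missing (NaN), never as zero.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    wides: dict[str, Optional[pd.DataFrame]] = {m: None for m in MEASURES}
    if rankings is not None and len(rankings):
        wides["rank"] = _wide(rankings[~rankings["include_death"].astype(bool)], "rank")
    if ratings is not None and len(ratings):
        dead = ratings["include_death"].astype(bool)
        wides["vas"] = _wide(ratings[~dead], "rating")
        if dead.any():
            wides["vas_death"] = _wide(ratings[dead], "rating")
    if elicitation is not None and len(elicitation):
        wides["utility"] = _wide(elicitation, "utility")

    out: dict[str, list[float]] = {}
    index = pd.MultiIndex.from_tuples(_rows(), names=["group", "quality"])
    for measure in MEASURES:
        wide = wides[measure]
        med, iqr, q1s, q3s, ns = [], [], [], [], []
        for group, quality in _rows():
            if wide is None:
                med.append(np.nan); iqr.append(np.nan)
                q1s.append(np.nan); q3s.append(np.nan); ns.append(0)
                continue
            s = group_scores(wide, group, quality, aggregate).dropna()
            if len(s) == 0:
                med.append(np.nan); iqr.append(np.nan)
                q1s.append(np.nan); q3s.append(np.nan); ns.append(0)
                continue
            q1, q2, q3 = np.percentile(s, [25, 50, 75])
            med.append(q2); iqr.append(q3 - q1); q1s.append(q1); q3s.append(q3)
            ns.append(int(len(s)))
        out[f"{measure}_median"] = med
        out[f"{measure}_iqr"] = iqr
        out[f"{measure}_q1"] = q1s
        out[f"{measure}_q3"] = q3s
        out[f"{measure}_n"] = ns
    return pd.DataFrame(out, index=index)


# --------------------------------------------------------------------------- #
def default_candidate_frame(covariates: pd.DataFrame) -> pd.DataFrame:
    """Regression candidates engineered from the covariate table.

    Continuous scores enter as-is; clinical categoricals enter as the
    contrasts the study reports (cancer in one breast, BMI category with
    'normal' as reference, bilateral plan, post-mastectomy timing) plus
    sociodemographic indicators.  Race is left out by default: with a
    40-woman cohort its minority levels hold a single participant each.
    """
    out = pd.DataFrame(index=covariates.index)
    for c in ("breastq_breast", "breastq_outcome", "asir_behavior",
              "asir_self_evaluation", "asir_control", "age"):
        if c in covariates:
            out[c] = covariates[c].astype(float)
    if "indication" in covariates:
        out["cancer_one_breast"] = (
            covariates["indication"].astype(str) == "cancer_one_breast"
        ).astype(float)
    if "bmi_category" in covariates:
        out["bmi_category"] = pd.Categorical(
            covariates["bmi_category"].astype(str),
            categories=["normal", "overweight", "obese"],
        )
    if "laterality" in covariates:
        out["bilateral"] = (covariates["laterality"].astype(str) == "bilateral").astype(float)
    if "timing" in covariates:
        out["post_mastectomy"] = (
            covariates["timing"].astype(str) == "post_mastectomy"
        ).astype(float)
    if "married" in covariates:
        out["married"] = (covariates["married"].astype(str) == "married").astype(float)
    if "education" in covariates:
        out["college_educated"] = (
            covariates["education"].astype(str) == "college_graduate_or_higher"
        ).astype(float)
    if "ethnicity" in covariates:
        out["hispanic"] = (covariates["ethnicity"].astype(str) == "hispanic").astype(float)
    return out


@dataclass
class PreferenceStudyResults:
    """Fitted summaries, tests, and regression models of a preference study."""

    summary_table: pd.DataFrame
    tests: pd.DataFrame
    models: dict[str, RegressionModel]
    n_participants: int
    completeness: dict[str, int]
    unexpected_fraction: float = float("nan")

    def regression_table(self) -> pd.DataFrame:
        """All retained coefficients across the twelve models, long format."""
        frames = []
        for key, model in self.models.items():
            t = model.terms.reset_index(names="term")
            t.insert(0, "model", key)
            t["aic"] = model.aic
            t["n"] = model.n
            frames.append(t)
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = []
        lines.append("Preference elicitation study results")
        lines.append("=" * 68)
        lines.append(f"participants: {self.n_participants}")
        comp = ", ".join(f"{m}={n}" for m, n in self.completeness.items())
        lines.append(f"complete responses per instrument: {comp}")
        if np.isfinite(self.unexpected_fraction):
            lines.append(
                f"unexpected rankings (fair/poor in top 3 or excellent in "
                f"bottom 3): {100 * self.unexpected_fraction:.0f}%"
            )
        lines.append("")
        lines.append("Medians (IQR) by option group and quality")
        lines.append("-" * 68)
        disp = pd.DataFrame(index=self.summary_table.index)
        for m, label in (("rank", "rank"), ("vas", "VAS"),
                         ("vas_death", "VAS+death"), ("utility", "utility")):
            disp[label] = [
                f"{med:.2f} ({iqr:.2f})" if np.isfinite(med) else "--"
                for med, iqr in zip(self.summary_table[f"{m}_median"],
                                    self.summary_table[f"{m}_iqr"])
            ]
        lines.append(disp.to_string())
        lines.append("")
        lines.append("Hypothesis tests")
        lines.append("-" * 68)
        cols = ["test", "measure", "grouping", "statistic", "p_value", "n"]
        lines.append(self.tests[cols].to_string(index=False,
                                                float_format=lambda v: f"{v:.4g}"))
        lines.append("")
        lines.append("Backward-AIC regression models (retained terms)")
        lines.append("-" * 68)
        for key, model in self.models.items():
            kept = model.terms[model.terms["block"] != "const"]
            lines.append(f"{key}  (AIC {model.aic:.1f}, n={model.n})")
            if len(kept) == 0:
                lines.append("    intercept only")
            else:
                for term, row in kept.iterrows():
                    lines.append(
                        f"    {term:<24s} B={row['coef']:8.3f}  "
                        f"CI [{row['ci_low']:.3f}, {row['ci_high']:.3f}]  "
                        f"p={row['p_value']:.4g}"
                    )
        return "\n".join(lines)

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.summary_table.reset_index().to_csv(
            os.path.join(outdir, "summary_table.csv"), index=False
        )
        self.tests.to_csv(os.path.join(outdir, "tests.csv"), index=False)
        self.regression_table().to_csv(
            os.path.join(outdir, "regressions.csv"), index=False
        )


class PreferenceStudy:
    """A preference-elicitation study ready to be analysed.

    Parameters
    ----------
    covariates : DataFrame
        One row per participant (``participant_id`` plus characteristics).
    elicitation, rankings, ratings : DataFrame, optional
        Long-format response tables as produced by the simulator or an
        interview capture: chained-gamble records (participant_id,
        state_id, p1, p2, utility, degenerate), rankings and VAS ratings
        (participant_id, state_id, include_death, rank/rating).
    """

    def __init__(
        self,
        covariates: pd.DataFrame,
        elicitation: Optional[pd.DataFrame] = None,
        rankings: Optional[pd.DataFrame] = None,
        ratings: Optional[pd.DataFrame] = None,
        config: Optional[GeneratorConfig] = None,
    ) -> None:
        if "participant_id" not in covariates.columns:
            raise ValueError("covariates table needs a participant_id column")
        self.covariates = covariates.reset_index(drop=True)
        self.elicitation = elicitation
        self.rankings = rankings
        self.ratings = ratings
        self.config = config

    # ------------------------------------------------------------------ #
    @classmethod
    def from_simulation(
        cls, config: Optional[GeneratorConfig] = None, seed: Optional[int] = None
    ) -> "PreferenceStudy":
        """Simulate a cohort and its interview under ``config`` (see
        :func:`reconpref.simulate.simulate_study`)."""
        sim = simulate_study(config, seed)
        return cls.from_simulated(sim)

    @classmethod
    def from_simulated(cls, sim: SimulatedStudy) -> "PreferenceStudy":
        return cls(sim.covariates, sim.elicitation, sim.rankings, sim.ratings,
                   config=sim.config)

    @classmethod
    def from_csv(cls, directory: str) -> "PreferenceStudy":
        """Load a study from ``cohort.csv`` plus any of ``elicitation.csv``,
        ``rankings.csv``, ``ratings.csv`` in ``directory``."""
        def _maybe(name):
            path = os.path.join(directory, name)
            return pd.read_csv(path) if os.path.exists(path) else None

        cov = pd.read_csv(os.path.join(directory, "cohort.csv"))
        return cls(cov, _maybe("elicitation.csv"), _maybe("rankings.csv"),
                   _maybe("ratings.csv"))

    # ------------------------------------------------------------------ #
    def _wides(self) -> dict[str, Optional[pd.DataFrame]]:
        wides: dict[str, Optional[pd.DataFrame]] = {m: None for m in MEASURES}
        if self.rankings is not None and len(self.rankings):
            mask = self.rankings["include_death"].astype(bool)
            wides["rank"] = _wide(self.rankings[~mask], "rank")
        if self.ratings is not None and len(self.ratings):
            mask = self.ratings["include_death"].astype(bool)
            wides["vas"] = _wide(self.ratings[~mask], "rating")
            if mask.any():
                wides["vas_death"] = _wide(self.ratings[mask], "rating")
        if self.elicitation is not None and len(self.elicitation):
            wides["utility"] = _wide(self.elicitation, "utility")
        return wides

    def unexpected_fraction(self) -> float:
        """Share of no-death rankings flagged as unexpected."""
        if self.rankings is None or not len(self.rankings):
            return float("nan")
        from .instruments import RankingRecord, flag_unexpected

        deck = build_deck("normal", "unilateral")
        flags = []
        sub = self.rankings[~self.rankings["include_death"].astype(bool)]
        for pid, grp in sub.groupby("participant_id", observed=True):
            rec = RankingRecord(str(pid), False,
                                dict(zip(grp["state_id"], grp["rank"])))
            flags.append(flag_unexpected(rec, deck)[0])
        return float(np.mean(flags)) if flags else float("nan")

    def fit(
        self,
        screen_alpha: float = 0.2,
        aggregate: str = "mean",
        candidates: Optional[pd.DataFrame] = None,
        test_method: str = "auto",
    ) -> PreferenceStudyResults:
        """Run the full analysis and return a results object.

        ``screen_alpha`` is the univariate retention threshold (0.2 in the
        study); ``aggregate`` chooses how a participant's option-group
        score pools its states (mean by default); ``candidates`` overrides
        the engineered regression covariate frame.
        """
        wides = self._wides()
        summary = summarize(self.elicitation, self.rankings, self.ratings, aggregate)

        completeness = {
            m: int(w.dropna().shape[0]) if w is not None else 0
            for m, w in wides.items()
        }
        n_total = len(self.covariates)
        for m, n_ok in completeness.items():
            if 0 < n_ok < n_total:
                warnings.warn(
                    f"{n_total - n_ok} participant(s) dropped listwise from "
                    f"{m!r} analyses", stacklevel=2,
                )

        results: list[TestResult] = []
        meta: list[dict] = []

        def _scores(measure, group, quality="pooled"):
            w = wides[measure]
            if w is None:
                return None
            return group_scores(w, group, quality, aggregate)

        # instrument correlation (VAS-with-death vs chained utility) per row
        if wides["vas_death"] is not None and wides["utility"] is not None:
            for group, quality in _rows():
                a = _scores("vas_death", group, quality)
                b = _scores("utility", group, quality)
                both = pd.concat([a.rename("a"), b.rename("b")], axis=1).dropna()
                if len(both) >= 3:
                    r = rank_utility_correlation(both["a"], both["b"])
                    results.append(r)
                    meta.append({"test": "spearman", "measure": "vas_death~utility",
                                 "grouping": f"{group}/{quality}"})

        # paired contrasts
        for measure in MEASURES:
            if wides[measure] is None:
                continue
            recon = _scores(measure, "any")
            none = _scores(measure, "none")
            both = pd.concat([recon.rename("a"), none.rename("b")], axis=1).dropna()
            if len(both):
                results.append(paired_compare(both["a"], both["b"], method=test_method,
                                              grouping="reconstruction vs none"))
                meta.append({"test": "wilcoxon", "measure": measure,
                             "grouping": "reconstruction vs none"})
            imp = _scores(measure, "implant")
            tis = _scores(measure, "tissue")
            both = pd.concat([imp.rename("a"), tis.rename("b")], axis=1).dropna()
            if len(both):
                results.append(paired_compare(both["a"], both["b"], method=test_method,
                                              grouping="implant vs tissue"))
                meta.append({"test": "wilcoxon", "measure": measure,
                             "grouping": "implant vs tissue"})

        # BMI comparisons
        bmi = self.covariates.set_index("participant_id")["bmi_category"] \
            if "bmi_category" in self.covariates else None
        if bmi is not None:
            for measure in ("vas", "vas_death", "utility"):
                if wides[measure] is None:
                    continue
                for group in ("implant", "tissue"):
                    s = _scores(measure, group).dropna()
                    g = bmi.reindex(s.index)
                    keep = g.notna()
                    if keep.sum() >= 3 and g[keep].nunique() >= 2:
                        results.append(
                            bmi_compare(s[keep], g[keep].astype(str),
                                        method=test_method,
                                        grouping=f"{group} by BMI")
                        )
                        meta.append({"test": "kruskal_wallis", "measure": measure,
                                     "grouping": f"{group} by BMI"})

        tests = pd.DataFrame(
            [
                {**m, "statistic": r.statistic, "p_value": r.p_value, "n": r.n,
                 "degenerate": r.degenerate, "note": r.note}
                for m, r in zip(meta, results)
            ]
        )

        # regressions: 3 instruments x 4 option groups
        cand = candidates if candidates is not None else default_candidate_frame(
            self.covariates
        )
        cand = cand.set_axis(self.covariates["participant_id"], axis=0)
        models: dict[str, RegressionModel] = {}
        for measure in ("vas", "vas_death", "utility"):
            if wides[measure] is None:
                continue
            for group in GROUPS:
                y = _scores(measure, group)
                y = y.reindex(cand.index)
                ok = y.notna()
                if ok.sum() <= len(cand.columns) + 2:
                    continue
                screen = univariate_screen(y[ok], cand[ok], alpha=screen_alpha)
                key = f"{measure}:{group}"
                if not screen.retained:
                    models[key] = RegressionModel(
                        outcome=key,
                        terms=pd.DataFrame(
                            columns=["coef", "ci_low", "ci_high", "p_value", "block"]
                        ),
                        aic=float("nan"), n=int(ok.sum()),
                        retained=[], screened=[],
                        notes=["no covariate survived the univariate screen"],
                    )
                    continue
                models[key] = backward_aic(y[ok], cand[ok], screen.retained,
                                           outcome_name=key)

        return PreferenceStudyResults(
            summary_table=summary,
            tests=tests,
            models=models,
            n_participants=n_total,
            completeness=completeness,
            unexpected_fraction=self.unexpected_fraction(),
        )
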