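"""One-command pipeline: cohort -> elicitation -> instruments -> analysis.

``run_pipeline`` regenerates everything from a config and a seed, writes
the input tables and analysis outputs as CSV, renders the median/IQR
figures, and logs seeds, versions and listwise exclusions to stderr.  Two
runs with the same config and seed produce byte-identical CSV output.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from typing import Optional

import pandas as pd

from . import __version__
from .config import GeneratorConfig
from .simulate import SimulatedStudy, simulate_study
from .study import PreferenceStudy, PreferenceStudyResults

logger = logging.getLogger("reconpref")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kw):
            try:
                logger.info("stage %s: start", name)
                out = fn(*args, **kw)
                logger.info("stage %s: done", name)
                return out
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage-named rethrow
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("simulate")
def _simulate(config: GeneratorConfig, seed: Optional[int]) -> SimulatedStudy:
    return simulate_study(config, seed)


@_stage("write-inputs")
def _write_inputs(sim: SimulatedStudy, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    sim.covariates.to_csv(os.path.join(outdir, "cohort.csv"), index=False)
    sim.latent.to_csv(os.path.join(outdir, "latent_utilities.csv"), index=False)
    sim.elicitation.to_csv(os.path.join(outdir, "elicitation.csv"), index=False)
    sim.rankings.to_csv(os.path.join(outdir, "rankings.csv"), index=False)
    sim.ratings.to_csv(os.path.join(outdir, "ratings.csv"), index=False)


@_stage("analyze")
def _analyze(sim: SimulatedStudy) -> PreferenceStudyResults:
    study = PreferenceStudy.from_simulated(sim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # screen warnings are re-logged below
        return study.fit()


@_stage("figures")
def _figures(sim: SimulatedStudy, results: PreferenceStudyResults, outdir: str) -> None:
    from .plotting import plot_bmi_ratings, plot_instrument_medians

    fig = plot_instrument_medians(results.summary_table)
    fig.savefig(os.path.join(outdir, "fig_instrument_medians.png"), dpi=150)
    fig2 = plot_bmi_ratings(sim.ratings, sim.covariates)
    fig2.savefig(os.path.join(outdir, "fig_bmi_ratings.png"), dpi=150)
    import matplotlib.pyplot as plt

    plt.close(fig)
    plt.close(fig2)


def run_pipeline(
    config: Optional[GeneratorConfig] = None,
    outdir: str = "reconpref_out",
    seed: Optional[int] = None,
    make_figures: bool = True,
) -> PreferenceStudyResults:
    """Run the whole study end to end and write all outputs to ``outdir``."""
    config = (config or GeneratorConfig()).validate()
    if seed is not None:
        config = config.replace(rng_seed=int(seed) % 2**31)
    logger.info("pipeline start: n=%d seed=%d reconpref %s",
                config.n_participants, config.rng_seed, __version__)

    sim = _simulate(config, None)
    _write_inputs(sim, outdir)
    results = _analyze(sim)
    results.save(outdir)
    for m, n_ok in results.completeness.items():
        if n_ok < results.n_participants:
            logger.info("listwise exclusions for %s: %d of %d participants kept",
                        m, n_ok, results.n_participants)
    if make_figures:
        _figures(sim, results, outdir)

    import numpy
    import scipy
    import statsmodels

    info = {
        "seed": config.rng_seed,
        "n_participants": config.n_participants,
        "reconpref": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "unexpected_fraction": results.unexpected_fraction,
    }
    with open(os.path.join(outdir, "run_info.json"), "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)
    logger.info("pipeline done: outputs in %s", outdir)
    return results
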