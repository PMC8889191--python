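"""Pipeline orchestration, power-table grids and test fixtures.

Ties the stages together — stimulus generation, cohort simulation, power
grids and quiz analysis — behind a single :func:`run_pipeline` entry point
driven by a plain dict (typically loaded from YAML/JSON), and provides
:func:`generate_fixtures`, a deterministic producer of small datasets used
by the unit tests and the worked examples.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from .cohort import CohortConfig, LearnerModel, QuizModel, simulate_cohort
from .power import (
    PowerResult,
    power_earnings_ttest,
    power_quiz_regression,
    power_quiz_ttest,
)
from .quiz import QuizItem, QuizKey
from .stimulus import generate_stimulus_set

__all__ = [
    "power_grid",
    "run_pipeline",
    "generate_fixtures",
    "make_fixture_quiz_key",
]

#: Scenario grids of the three study power tables.
GRID_N = (50, 75, 100)
GRID_PLEARN = (0.0, 0.25, 0.33, 0.50)
GRID_GAIN = (1, 2)


def power_grid(
    table: int,
    seed: int | None = None,
    n_iterations: int = 500,
    alpha: float = 0.0322,
    model: LearnerModel | None = None,
) -> pd.DataFrame:
    """Compute one of the three study power grids.

    Table 1: earnings paired t-test over N x plearn.  Table 2: quiz paired
    t-test over gain x N x plearn.  Table 3: transfer regression over
    gain x N x plearn.  Returns a tidy DataFrame with power and its
    Monte-Carlo standard error per cell.
    """
    if table not in (1, 2, 3):
        raise ValueError("table must be 1, 2 or 3")
    root = np.random.default_rng(seed)
    rows = []
    gains: Sequence[int | None] = (None,) if table == 1 else GRID_GAIN
    for gain in gains:
        for n in GRID_N:
            for plearn in GRID_PLEARN:
                cfg = CohortConfig(
                    n_participants=n, plearn=plearn, n_iterations=n_iterations, alpha=alpha
                )
                rng = root.spawn(1)[0]
                if table == 1:
                    res = power_earnings_ttest(cfg, model=model, rng=rng)
                elif table == 2:
                    res = power_quiz_ttest(cfg, quiz=QuizModel(gain_items=gain), rng=rng)
                else:
                    res = power_quiz_regression(
                        cfg, model=model, quiz=QuizModel(gain_items=gain), rng=rng
                    )
                row = {
                    "test": res.test,
                    "N": n,
                    "plearn": plearn,
                    "power": res.power,
                    "mc_se": res.mc_std_error,
                    "n_iter": res.n_iterations,
                    "alpha": alpha,
                    "seed": seed,
                }
                if gain is not None:
                    row["gain_items"] = gain
                rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the stages requested in ``config`` and write their artifacts.

    Recognised stage blocks: ``stimulus`` (n_trials, prop_true, delta),
    ``cohort`` (n_participants, plearn), ``power`` (table, n_iterations).
    A top-level ``seed`` governs all randomness; a manifest with the seed,
    package version and parameters is written alongside the outputs.
    Returns a dict mapping stage names to the paths written.
    """
    seed = config.get("seed", 0)
    out_dir = Path(out_dir or config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    artifacts: dict[str, str] = {}

    if "stimulus" in config:
        p = config["stimulus"]
        trials = generate_stimulus_set(
            n_trials=int(p.get("n_trials", 80)),
            prop_true=float(p.get("prop_true", 0.5)),
            rng=root.spawn(1)[0],
            delta=float(p.get("delta", 0.3)),
        )
        io.write_stimulus_set(trials, out_dir / "stimulus", seed=seed)
        io.write_trajectories(trials, out_dir / "stimulus" / "trajectories.csv")
        artifacts["stimulus"] = str(out_dir / "stimulus")

    if "cohort" in config:
        p = config["cohort"]
        cfg = CohortConfig(
            n_participants=int(p.get("n_participants", 100)),
            plearn=float(p.get("plearn", 0.5)),
        )
        df = simulate_cohort(cfg, rng=root.spawn(1)[0])
        io.write_cohort(df, out_dir / "cohort.csv", seed=seed)
        artifacts["cohort"] = str(out_dir / "cohort.csv")

    if "power" in config:
        p = config["power"]
        grid = power_grid(
            table=int(p.get("table", 1)),
            seed=seed,
            n_iterations=int(p.get("n_iterations", 500)),
            alpha=float(p.get("alpha", 0.0322)),
        )
        path = out_dir / f"power_table{p.get('table', 1)}.csv"
        grid.to_csv(path, index=False)
        artifacts["power"] = str(path)

    io.write_manifest(out_dir, seed=seed, config=config, artifacts=artifacts)
    return artifacts


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixture_quiz_key() -> QuizKey:
    """A synthetic two-form answer key with the study's item structure.

    Twelve items per form, six P and six S; options are labelled A-D with
    the correct option and (for S-items except item 3) a designated bias
    foil.  Item text is not modelled — scoring only needs the key.
    """
    items = []
    for form, suffix in ((1, "A"), (2, "B")):
        for i in range(1, 7):
            items.append(
                QuizItem(
                    item_id=f"P{i}{suffix}",
                    form=form,
                    item_type="P",
                    correct_option="A",
                    bias_foil=None,
                    other_foils=("B", "C", "D"),
                )
            )
        for i in range(1, 7):
            has_bias = i != 3  # item 3 has no sample-size-neglect foil
            items.append(
                QuizItem(
                    item_id=f"S{i}{suffix}",
                    form=form,
                    item_type="S",
                    correct_option="A",
                    bias_foil="B" if has_bias else None,
                    other_foils=("C", "D") if has_bias else ("B", "C", "D"),
                )
            )
    return QuizKey(items)


def _simulate_answer_sheets(
    key: QuizKey, n_participants: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Synthetic answer sheets with errors clustered on the bias foil."""
    rows = []
    for pid in range(1, n_participants + 1):
        pre_form = 1 if pid % 2 else 2
        for session, form in (("pre", pre_form), ("post", 3 - pre_form)):
            for item in key.items.values():
                if item.form != form:
                    continue
                p_correct = 0.75 if item.item_type == "P" else 0.3
                if rng.random() < p_correct:
                    choice = item.correct_option
                elif item.bias_foil is not None and rng.random() < 0.6:
                    choice = item.bias_foil
                else:
                    choice = item.other_foils[int(rng.integers(len(item.other_foils)))]
                rows.append(
                    {
                        "participant_id": pid,
                        "session": session,
                        "form": form,
                        "item_id": item.item_id,
                        "choice": choice,
                    }
                )
    return pd.DataFrame(rows)


def generate_fixtures(seed: int = 0, out_dir: str | Path | None = None) -> dict:
    """Produce the small deterministic datasets used by tests and examples.

    Returns a dict with an 8-trial stimulus set (4 true / 4 null), a
    10-participant cohort table, the two-form quiz key and synthetic answer
    sheets for 20 participants.  With ``out_dir`` set, everything is also
    written to disk.
    """
    root = np.random.default_rng(seed)
    trials = generate_stimulus_set(8, 0.5, root.spawn(1)[0])
    cohort = simulate_cohort(
        CohortConfig(n_participants=10, plearn=0.5), rng=root.spawn(1)[0]
    )
    key = make_fixture_quiz_key()
    sheets = _simulate_answer_sheets(key, 20, root.spawn(1)[0])
    out = {"stimuli": trials, "cohort": cohort, "quiz_key": key, "quiz_responses": sheets}
    if out_dir is not None:
        out_dir = Path(out_dir)
        io.write_stimulus_set(trials, out_dir / "stimulus", seed=seed)
        io.write_cohort(cohort, out_dir / "cohort.csv", seed=seed)
        key.to_frame().to_csv(out_dir / "quiz_key.csv", index=False)
        sheets.to_csv(out_dir / "quiz_responses.csv", index=False)
        io.write_manifest(out_dir, seed=seed, fixtures=sorted(out))
    return out
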