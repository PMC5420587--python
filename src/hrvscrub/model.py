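"""End-to-end sleep-scrubbing reliability analysis as a Model/Results pair.

:class:`SleepScrubReliability` is built from a two-session cohort (simulated
or loaded from disk). Its :meth:`~SleepScrubReliability.fit` runs the whole
chain — sliding-window HRV, percentile volume censoring, Pearson/Fisher-z
connectivity, weighted graph metrics, unit- and scan-wise ICC, and the
one-tailed permutation test against the random-censoring null — and returns a
:class:`SleepScrubResults` carrying the estimates, their null bounds and a
``summary()`` table. The percentile and window-length sweeps hang off the
model object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import censoring, connectivity, graph, hrv, reliability
from .censoring import VolumeMask
from .connectivity import _z_matrix, fc_matrix
from .synthetic import Cohort, SimulationConfig, simulate_sessions

__all__ = ["SleepScrubReliability", "SleepScrubResults"]

DEFAULT_GRAPH_THRESHOLDS = (0.1, 0.3, 0.5)
DEFAULT_PERCENTILES = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3)

#: one-tailed test direction per censoring condition: alert volumes are
#: expected to raise reliability over random retention, sleepy to lower it
_CONDITION_TAILS = {"alert": "right", "sleepy": "left"}


class SleepScrubReliability:
    """HRV-based sleep-scrubbing reliability model for a two-session cohort.

    Parameters
    ----------
    cohort
        Complete cohort: beat times and ROI x volume tables for every subject
        in both sessions.
    metric
        Sleepiness index, ``"rmssd"`` or ``"cvi"``.
    window_length
        Sliding-window length in seconds (16 s default).
    graph_thresholds
        Correlation thresholds T_r for the weighted graphs.
    n_random_draws
        Size of the random-censoring null ensemble (5000 at full scale).
    """

    def __init__(
        self,
        cohort: Cohort,
        metric: str = "rmssd",
        window_length: float = 16.0,
        ectopic_threshold: float = 0.20,
        graph_thresholds: tuple = DEFAULT_GRAPH_THRESHOLDS,
        clustering: str = "weighted",
        n_random_draws: int = 5000,
    ) -> None:
        if metric not in hrv.MIN_INTERVALS:
            raise ValueError(f"unknown metric {metric!r}")
        missing = [
            (s, ses)
            for s in cohort.subjects
            for ses in cohort.sessions
            if (s, ses) not in cohort.roits or (s, ses) not in cohort.beats
        ]
        if missing:
            raise ValueError(f"incomplete cohort, missing {missing[:4]}")
        if len(cohort.sessions) < 2:
            raise ValueError("two sessions per subject required")
        self.cohort = cohort
        self.metric = metric
        self.window_length = float(window_length)
        self.ectopic_threshold = float(ectopic_threshold)
        self.graph_thresholds = tuple(graph_thresholds)
        self.clustering = clustering
        self.n_random_draws = int(n_random_draws)
        self._keys = [(s, ses) for s in cohort.subjects for ses in cohort.sessions]
        self._ibi_cache: dict = {}
        self._tv_cache: dict = {}

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_simulation(cls, config: SimulationConfig | None = None, **kwargs) -> "SleepScrubReliability":
        """Build the model on a freshly simulated default cohort."""
        return cls(simulate_sessions(config or SimulationConfig()), **kwargs)

    @classmethod
    def from_directory(cls, directory, tr: float | None = None, **kwargs) -> "SleepScrubReliability":
        """Build the model from a fixture tree on disk (see :mod:`hrvscrub.io`)."""
        from .io import read_cohort

        return cls(read_cohort(directory, tr=tr), **kwargs)

    # ------------------------------------------------------------ HRV plumbing
    def ibi(self, key: tuple) -> hrv.IBISeries:
        """Cleaned IBI series for one subject-session."""
        if key not in self._ibi_cache:
            raw = hrv.beats_to_ibi(self.cohort.beats[key])
            self._ibi_cache[key] = hrv.clean_ibi(raw, self.ectopic_threshold)
        return self._ibi_cache[key]

    def tv_hrv(self, window_length: float | None = None) -> dict:
        """Per-volume HRV for every subject-session at a window length."""
        w = self.window_length if window_length is None else float(window_length)
        if w not in self._tv_cache:
            self._tv_cache[w] = {
                key: hrv.sliding_hrv(
                    self.ibi(key), self.metric, w, self.cohort.tr, self.cohort.n_volumes
                )
                for key in self._keys
            }
        return self._tv_cache[w]

    def condition_masks(
        self, mode: str, percentile: float, window_length: float | None = None
    ) -> dict:
        """Sleepy/alert/whole retention masks for every subject-session."""
        tvs = self.tv_hrv(window_length)
        return {
            key: censoring.select_volumes(tvs[key], mode, percentile) for key in self._keys
        }

    def alertness_survival(
        self,
        threshold: float = 0.5,
        dropout_run: int = 5,
        session: str | None = None,
    ) -> censoring.SurvivalCurve:
        """Survival curve of continuously alert subjects in one session."""
        ses = session or self.cohort.sessions[0]
        tvs = self.tv_hrv()
        masks = [
            censoring.select_volumes(tvs[(s, ses)], "sleepy", threshold)
            for s in self.cohort.subjects
        ]
        return censoring.alertness_survival(masks, dropout_run=dropout_run, threshold=threshold)

    # ------------------------------------------------------------ measures
    def measure_names(self) -> list[str]:
        names = ["fc"]
        for t in self.graph_thresholds:
            names += [f"degree_t{t:g}", f"clustering_t{t:g}"]
        return names

    def _measure_tables(self, masks: dict) -> dict:
        """units x subjects x sessions table per measure for given masks."""
        n_sub = len(self.cohort.subjects)
        n_ses = len(self.cohort.sessions)
        per_key: dict = {name: {} for name in self.measure_names()}
        for key in self._keys:
            cm = fc_matrix(self.cohort.roits[key], masks[key])
            iu = np.triu_indices(cm.n_rois, k=1)
            per_key["fc"][key] = _z_matrix(cm)[iu]
            for t in self.graph_thresholds:
                adj = graph.threshold_matrix(cm, t)
                per_key[f"degree_t{t:g}"][key] = graph.degree_centrality(adj).values
                per_key[f"clustering_t{t:g}"][key] = graph.clustering_coefficient(
                    adj, kind=self.clustering
                ).values
        tables = {}
        for name, d in per_key.items():
            n_units = d[self._keys[0]].size
            cube = np.empty((n_units, n_sub, n_ses))
            for i, s in enumerate(self.cohort.subjects):
                for j, ses in enumerate(self.cohort.sessions):
                    cube[:, i, j] = d[(s, ses)]
            tables[name] = cube
        return tables

    @staticmethod
    def _iccs(table: np.ndarray) -> tuple:
        # degenerate measures (e.g. an empty graph at a high threshold for
        # every subject) surface as NaN rather than aborting the run
        try:
            unit = reliability.unit_wise_icc(table).unit_wise
        except ValueError:
            unit = float("nan")
        scan = reliability.scan_wise_icc(table)
        return unit, scan

    def _random_null(
        self, percentile: float, n_draws: int, seed: int | None
    ) -> dict:
        """Null ICC distributions from random retention masks.

        One ensemble of masks per draw is shared across all measures (the
        random condition controls for volume count, so FC and graph measures
        see the same retained volumes).
        """
        rng = np.random.default_rng(seed)
        n_vol = self.cohort.n_volumes
        k = censoring._round_count(percentile * n_vol)
        null = {name: {"unit": [], "scan": []} for name in self.measure_names()}
        for _ in range(n_draws):
            masks = {}
            for key in self._keys:
                retained = np.zeros(n_vol, dtype=bool)
                retained[rng.choice(n_vol, size=k, replace=False)] = True
                masks[key] = VolumeMask(mode="random", percentile=percentile, retained=retained)
            for name, table in self._measure_tables(masks).items():
                unit, scan = self._iccs(table)
                null[name]["unit"].append(unit)
                null[name]["scan"].append(scan)
        return {
            name: {lvl: np.asarray(v) for lvl, v in d.items()} for name, d in null.items()
        }

    # ------------------------------------------------------------ fitting
    def fit(
        self,
        percentile: float = 0.5,
        modes: tuple = ("sleepy", "alert", "whole"),
        seed: int = 0,
        n_random_draws: int | None = None,
    ) -> "SleepScrubResults":
        """Run the analysis at one retention percentile.

        Computes unit- and scan-wise ICC for functional connectivity and both
        graph metrics at every threshold, for each requested censoring mode,
        plus the random-censoring null and one-tailed permutation p-values
        for the sleepy (left tail) and alert (right tail) conditions.
        """
        n_draws = self.n_random_draws if n_random_draws is None else int(n_random_draws)
        observed: dict = {}
        for mode in modes:
            p = 1.0 if mode == "whole" else percentile
            masks = self.condition_masks(mode, p)
            observed[mode] = {
                name: self._iccs(table) for name, table in self._measure_tables(masks).items()
            }
        null = self._random_null(percentile, n_draws, seed)

        rows = []
        for name in self.measure_names():
            for li, level in enumerate(("unit", "scan")):
                null_vec = null[name][level]
                for mode in modes:
                    value = observed[mode][name][li]
                    tail = _CONDITION_TAILS.get(mode)
                    if tail is not None:
                        perm = reliability.permutation_test(value, null_vec, tail)
                        p_val, sig = perm.p_value, perm.significant
                    else:
                        p_val, sig = np.nan, False
                    rows.append(
                        {
                            "measure": name,
                            "level": level,
                            "mode": mode,
                            "icc": value,
                            "band": reliability.icc_band(value),
                            "p_vs_random": p_val,
                            "significant": sig,
                            "null_mean": float(null_vec.mean()),
                            "null_lo": float(np.percentile(null_vec, 5)),
                            "null_hi": float(np.percentile(null_vec, 95)),
                        }
                    )
                rows.append(
                    {
                        "measure": name,
                        "level": level,
                        "mode": "random",
                        "icc": float(null_vec.mean()),
                        "band": reliability.icc_band(float(null_vec.mean())),
                        "p_vs_random": np.nan,
                        "significant": False,
                        "null_mean": float(null_vec.mean()),
                        "null_lo": float(np.percentile(null_vec, 5)),
                        "null_hi": float(np.percentile(null_vec, 95)),
                    }
                )
        table = pd.DataFrame(rows)
        return SleepScrubResults(
            model=self,
            table=table,
            percentile=percentile,
            seed=seed,
            n_random_draws=n_draws,
            null=null,
        )

    # ------------------------------------------------------------ sweeps
    def percentile_sweep(
        self,
        percentiles: tuple = DEFAULT_PERCENTILES,
        modes: tuple = ("sleepy", "alert"),
        seed: int = 0,
        n_random_draws: int | None = None,
    ) -> pd.DataFrame:
        """ICC versus retention percentile for each mode and measure.

        Each percentile gets its own random null (same volume count); rows
        carry the null mean and 5/95 bounds with significance flags where the
        observed ICC falls outside them.
        """
        frames = []
        for i, p in enumerate(percentiles):
            res = self.fit(
                percentile=p, modes=modes, seed=seed + i, n_random_draws=n_random_draws
            )
            df = res.table.copy()
            df.insert(0, "percentile", p)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def window_sweep(
        self,
        candidates: tuple = hrv.DEFAULT_WINDOW_CANDIDATES,
        percentile: float = 0.5,
        seed: int = 0,
        n_random_draws: int | None = None,
    ) -> tuple:
        """Window-length selection report plus reliability per window length.

        Repeats the sleepy/alert analysis across the candidate grid and
        bundles it with the consistency-ratio / ICC selection diagnostics.
        """
        ibi_by_key = {key: self.ibi(key) for key in self._keys}
        report = hrv.window_selection_report(
            candidates, ibi_by_key, self.cohort.tr, self.cohort.n_volumes, self.metric
        )
        rows = []
        for i, w in enumerate(candidates):
            for mode in ("sleepy", "alert"):
                masks = self.condition_masks(mode, percentile, window_length=w)
                for name, table in self._measure_tables(masks).items():
                    unit, scan = self._iccs(table)
                    rows.append(
                        {
                            "window_length": w,
                            "mode": mode,
                            "measure": name,
                            "unit_wise_icc": unit,
                            "scan_wise_icc": scan,
                        }
                    )
        return report, pd.DataFrame(rows)


@dataclass
class SleepScrubResults:
    """Fitted reliability estimates with their random-censoring null."""

    model: SleepScrubReliability
    table: pd.DataFrame
    percentile: float
    seed: int
    n_random_draws: int
    null: dict = field(repr=False, default_factory=dict)

    def icc(self, measure: str, level: str, mode: str) -> float:
        sel = self.table[
            (self.table["measure"] == measure)
            & (self.table["level"] == level)
            & (self.table["mode"] == mode)
        ]
        if sel.empty:
            raise KeyError((measure, level, mode))
        return float(sel.icc.iloc[0])

    def summary(self) -> str:
        """Human-readable report of every ICC against its random null."""
        lines = [
            "Sleep-scrubbing reliability analysis",
            "=" * 68,
            f"metric: {self.model.metric}   window: {self.model.window_length:g} s   "
            f"retention: {self.percentile:g}   null draws: {self.n_random_draws}",
            f"subjects: {len(self.model.cohort.subjects)}   "
            f"volumes: {self.model.cohort.n_volumes}   TR: {self.model.cohort.tr:g} s",
            "-" * 68,
            f"{'measure':<18}{'level':<6}{'mode':<8}{'ICC':>8}{'band':>11}{'p':>9}",
            "-" * 68,
        ]
        for _, row in self.table.iterrows():
            p = "" if not np.isfinite(row.p_vs_random) else f"{row.p_vs_random:.4f}"
            star = "*" if row.significant else ""
            lines.append(
                f"{row.measure:<18}{row.level:<6}{row['mode']:<8}"
                f"{row.icc:>8.3f}{row.band:>11}{p:>8}{star}"
            )
        lines.append("-" * 68)
        lines.append("* one-tailed permutation p < 0.05 against random censoring")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")
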