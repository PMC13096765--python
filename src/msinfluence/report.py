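"""Diagnostic workflows and tab-separated report writers.

``run_diagnose`` ties the modules into the standard workflow: fit the
multistate Cox model, compute the requested case-weight schemes and the
case-deletion measures, and write per-scheme tables, index-plot data, and
a flag summary.  ``run_compare`` refits after removing chosen patients and
writes a side-by-side coefficient table with Wald p-values.  All outputs
are plain tab-separated text at full precision; identical inputs and seeds
reproduce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data import MultistateDataset, read_long_format
from .graph import get_preset, load_graph_config
from .influence_global import GlobalInfluenceResult, global_influence
from .influence_local import (CurvatureResult, curvature_matrix, delta_scheme1,
                              delta_scheme2, delta_scheme3, hmax)
from .likelihood import FittedModel, fit, nelson_aalen_baseline

__all__ = [
    "load_graph",
    "load_dataset",
    "write_fit_report",
    "comparison_table",
    "run_diagnose",
    "run_compare",
]

_SCHEMES = {"1": delta_scheme1, "2": delta_scheme2, "3": delta_scheme3}


def load_graph(spec: str):
    """Resolve a graph argument: preset name or YAML config path."""
    path = Path(spec)
    if path.exists():
        return load_graph_config(path)[0]
    return get_preset(spec)


def load_dataset(data_path, graph_spec: str) -> MultistateDataset:
    return read_long_format(data_path, load_graph(graph_spec))


def _write(frame: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def write_fit_report(fitted: FittedModel, out_dir) -> dict[str, Path]:
    """Coefficient table, per-transition event counts, and baselines."""
    out = Path(out_dir)
    paths = {}
    coef = fitted.summary_frame().reset_index(names="covariate")
    paths["coefficients"] = _write(coef, out / "coefficients.tsv")
    counts = pd.DataFrame({
        "trans": [ev.g for ev in fitted.events],
        "n_records": [n for n in fitted.dataset.n_per_transition.values()],
        "n_events": [len(ev.event_rows) for ev in fitted.events],
    })
    paths["transition_counts"] = _write(counts, out / "transition_counts.tsv")
    for ev in fitted.events:
        base = nelson_aalen_baseline(fitted, ev.g)
        paths[f"baseline_{ev.g}"] = _write(base, out / f"baseline_trans{ev.g}.tsv")
    return paths


def _scheme_frame(result: CurvatureResult) -> pd.DataFrame:
    frame = result.to_frame()
    h = hmax(result)
    frame["abs_hmax"] = np.abs(h)
    return frame


def _index_plot_frame(result: CurvatureResult) -> pd.DataFrame:
    """Scheme I index-plot data: x = within-transition index, panel = transition."""
    trans = [lab[0] for lab in result.labels]
    idx, seen = [], {}
    for g in trans:
        seen[g] = seen.get(g, 0) + 1
        idx.append(seen[g])
    return pd.DataFrame({
        "trans": trans,
        "index": idx,
        "patient": [lab[1] for lab in result.labels],
        "B_i": result.B_i,
        "cutoff": result.cutoff,
    })


def comparison_table(full: FittedModel, reduced: FittedModel) -> pd.DataFrame:
    """Side-by-side coefficients, SEs and Wald p-values, full vs reduced fit."""
    def cols(m: FittedModel, tag: str) -> dict:
        se = m.standard_errors
        z = np.divide(m.beta, se, out=np.zeros_like(m.beta), where=se > 0)
        return {f"coef_{tag}": m.beta, f"se_{tag}": se,
                f"p_{tag}": 2 * stats.norm.sf(np.abs(z))}
    out = pd.DataFrame({"covariate": full.covariates})
    for k, v in {**cols(full, "full"), **cols(reduced, "reduced")}.items():
        out[k] = v
    return out


def run_diagnose(data_path, graph_spec: str, schemes=("1", "2", "3", "global"),
                 out_dir="diagnostics", exact: bool = False) -> dict[str, Path]:
    """Fit the model and write the requested diagnostic tables.

    ``schemes`` is any non-empty subset of {"1", "2", "3", "global"}.
    Scheme tables carry (label, B_i, cutoff, flag, |hmax|); Scheme I also
    gets per-transition index-plot data.  A summary counts flagged units
    per scheme (and per transition for Scheme I).
    """
    schemes = [str(s) for s in schemes]
    bad = [s for s in schemes if s not in {"1", "2", "3", "global"}]
    if bad:
        raise ValueError(f"unknown scheme(s) {bad}; choose from 1, 2, 3, global")
    if not schemes:
        raise ValueError("at least one scheme is required")
    data = load_dataset(data_path, graph_spec)
    fitted = fit(data)
    out = Path(out_dir)
    paths = write_fit_report(fitted, out)
    summary_rows = []
    for s in schemes:
        if s == "global":
            gi = global_influence(fitted, exact=exact)
            paths["global"] = _write(gi.to_frame(), out / "global_influence.tsv")
            summary_rows.append(["global", len(gi.flagged)])
            continue
        result = curvature_matrix(fitted, _SCHEMES[s](fitted))
        paths[f"scheme{s}"] = _write(_scheme_frame(result), out / f"scheme{s}.tsv")
        summary_rows.append([f"scheme{s}", len(result.flagged)])
        if s == "1":
            ip = _index_plot_frame(result)
            paths["scheme1_index_plot"] = _write(ip, out / "scheme1_index_plot.tsv")
            flagged_g = ip.loc[ip["B_i"] > ip["cutoff"], "trans"].value_counts()
            for g in sorted(flagged_g.index):
                summary_rows.append([f"scheme1_trans{g}", int(flagged_g[g])])
    summary = pd.DataFrame(summary_rows, columns=["scheme", "n_flagged"])
    paths["summary"] = _write(summary, out / "summary.tsv")
    return paths


def run_compare(data_path, graph_spec: str, remove_ids, out_dir="comparison",
                out_name: str = "comparison.tsv") -> Path:
    """Refit without the given patients and write the comparison table."""
    data = load_dataset(data_path, graph_spec)
    full = fit(data)
    reduced = fit(data.without_patients(remove_ids), covariates=full.covariates,
                  init=full.beta)
    return _write(comparison_table(full, reduced), Path(out_dir) / out_name)


def flagged_patients_from_run(run_dir) -> list[str]:
    """Patient ids flagged by Scheme III (falling back to the global table)
    in a previous ``run_diagnose`` output directory."""
    run = Path(run_dir)
    for name, col in (("scheme3.tsv", "label"), ("global_influence.tsv", "id")):
        path = run / name
        if path.exists():
            tab = pd.read_csv(path, sep="\t", dtype={col: str})
            return tab.loc[tab["flag"] == 1, col].tolist()
    raise FileNotFoundError(f"no scheme3.tsv or global_influence.tsv under {run}")
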