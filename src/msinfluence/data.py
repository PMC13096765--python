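"""Long-format clock-reset multistate event-history data.

One row per patient-at-risk-for-transition: whenever a patient occupies a
state, they contribute one record for every transition leaving that state,
all sharing the same sojourn interval; the record for the transition
actually taken (if any) carries ``status = 1``, the competing records are
censored at the same time.  Times are in months; each record's clock starts
at 0 on entry to its origin state (clock-reset convention), so the at-risk
interval is the half-open ``(0, Tstop - Tstart]``.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import CovariateMapping, TransitionGraph

__all__ = [
    "LONG_COLUMNS",
    "TransitionRecord",
    "MultistateDataset",
    "RelapseTimes",
    "read_long_format",
    "write_long_format",
    "resolve_simultaneous_relapse",
    "truncate_covariate",
    "expand_covariates",
]

#: Mandatory header of the long format; covariate columns follow.
LONG_COLUMNS = ["id", "from", "to", "trans", "Tstart", "Tstop", "status"]


@dataclass(frozen=True)
class TransitionRecord:
    """A single patient-at-risk-for-transition row (clock-reset times)."""

    patient_id: str
    transition_id: int
    entry_time: float
    exit_time: float
    status: int
    covariates: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.exit_time > self.entry_time >= 0:
            raise ValueError(
                f"record ({self.patient_id}, g={self.transition_id}): need "
                f"exit_time > entry_time >= 0, got ({self.entry_time}, {self.exit_time}]"
            )
        if self.status not in (0, 1):
            raise ValueError(f"status must be 0 or 1, got {self.status}")


class MultistateDataset:
    """Validated long-format dataset bound to a transition graph.

    Attributes
    ----------
    graph
        The :class:`~msinfluence.graph.TransitionGraph`.
    table
        The long-format rows (``LONG_COLUMNS`` + covariate columns), in
        file order.
    covariates
        Names of the covariate (design) columns.
    """

    def __init__(self, graph: TransitionGraph, table: pd.DataFrame,
                 covariates: Sequence[str] | None = None) -> None:
        self.graph = graph
        if covariates is None:
            covariates = [c for c in table.columns if c not in LONG_COLUMNS]
        self.covariates = list(covariates)
        missing = [c for c in LONG_COLUMNS + self.covariates if c not in table.columns]
        if missing:
            raise ValueError(f"dataset table missing columns {missing}")
        self.table = table.reset_index(drop=True)
        self._validate()

    # -- dimensions ---------------------------------------------------------
    @property
    def n_records(self) -> int:
        """Total number of (transition, patient) components N."""
        return len(self.table)

    @property
    def n_per_transition(self) -> dict[int, int]:
        """N_g: number of records per transition."""
        counts = self.table["trans"].value_counts()
        return {g: int(counts.get(g, 0)) for g in range(1, self.graph.n_transitions + 1)}

    @property
    def patient_ids(self) -> list[str]:
        """Distinct patient ids in file order (the dense index order)."""
        return list(dict.fromkeys(self.table["id"]))

    @property
    def n_patients(self) -> int:
        """M, the number of patients in the study."""
        return len(self.patient_ids)

    def membership(self) -> pd.DataFrame:
        """Indicator I_gi: 1 iff patient i has a record for transition g.

        Rows are patients (file order), columns transitions 1..G.
        """
        ids = self.patient_ids
        idx = {pid: k for k, pid in enumerate(ids)}
        mat = np.zeros((len(ids), self.graph.n_transitions), dtype=int)
        for pid, g in zip(self.table["id"], self.table["trans"]):
            mat[idx[pid], g - 1] = 1
        return pd.DataFrame(mat, index=ids, columns=range(1, self.graph.n_transitions + 1))

    @property
    def duration(self) -> pd.Series:
        """Clock-reset at-risk durations Tstop - Tstart."""
        return self.table["Tstop"] - self.table["Tstart"]

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        t = self.table
        bad = ~t["trans"].isin(range(1, self.graph.n_transitions + 1))
        if bad.any():
            rows = (t.index[bad] + 1).tolist()
            raise ValueError(f"unknown transition id in row(s) {rows}")
        dur = t["Tstop"] - t["Tstart"]
        bad = ~(dur > 0)
        if bad.any():
            rows = (t.index[bad] + 1).tolist()
            raise ValueError(f"non-positive at-risk duration in row(s) {rows}")
        if (t["Tstart"] < 0).any():
            rows = (t.index[t["Tstart"] < 0] + 1).tolist()
            raise ValueError(f"negative Tstart in row(s) {rows}")
        if not t["status"].isin((0, 1)).all():
            rows = (t.index[~t["status"].isin((0, 1))] + 1).tolist()
            raise ValueError(f"status outside {{0,1}} in row(s) {rows}")
        dup = t.duplicated(subset=["id", "trans"], keep=False)
        if dup.any():
            pairs = sorted(set(zip(t.loc[dup, "id"], t.loc[dup, "trans"])))
            raise ValueError(f"duplicated (id, trans) pair(s): {pairs}")
        # from/to must agree with the graph's transition table
        for g in sorted(t["trans"].unique()):
            i, j = self.graph.transitions[g - 1]
            sub = t[t["trans"] == g]
            mism = (sub["from"] != i) | (sub["to"] != j)
            if mism.any():
                rows = (sub.index[mism] + 1).tolist()
                raise ValueError(
                    f"row(s) {rows}: trans={g} must connect {i}->{j} per the graph"
                )

    # -- convenience --------------------------------------------------------
    def records(self) -> Iterable[TransitionRecord]:
        for _, r in self.table.iterrows():
            yield TransitionRecord(
                patient_id=str(r["id"]),
                transition_id=int(r["trans"]),
                entry_time=0.0,
                exit_time=float(r["Tstop"] - r["Tstart"]),
                status=int(r["status"]),
                covariates=tuple(float(r[c]) for c in self.covariates),
            )

    def without_patients(self, ids: Iterable[str]) -> "MultistateDataset":
        """New dataset with every record of the given patients removed."""
        drop = set(str(i) for i in ids)
        keep = ~self.table["id"].astype(str).isin(drop)
        return MultistateDataset(self.graph, self.table[keep].copy(), self.covariates)

    def copy(self) -> "MultistateDataset":
        return MultistateDataset(self.graph, self.table.copy(), list(self.covariates))


def _read_table(path) -> pd.DataFrame:
    # auto-detect comma vs tab from the header line
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    header = text.splitlines()[0] if text else ""
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(io.StringIO(text), sep=sep)


def read_long_format(path, graph: TransitionGraph) -> MultistateDataset:
    """Read delimited long-format multistate data (comma or tab).

    Expects the header ``id, from, to, trans, Tstart, Tstop, status``
    followed by covariate columns.  Malformed rows are rejected with
    1-based row numbers in the error message.
    """
    table = _read_table(path)
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    table["id"] = table["id"].astype(str)
    for c in table.columns:
        if c != "id":
            table[c] = pd.to_numeric(table[c])
    for c in ("from", "to", "trans", "status"):
        table[c] = table[c].astype(int)
    return MultistateDataset(graph, table)


def write_long_format(data: MultistateDataset, path, sep: str = "\t") -> None:
    """Write the dataset back out; numeric content round-trips exactly."""
    data.table.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class RelapseTimes:
    """Adjusted local/distant relapse times for one patient."""

    local: float | None
    distant: float | None
    dropped: bool = False


def resolve_simultaneous_relapse(local: float | None,
                                 distant: float | None) -> RelapseTimes:
    """Enforce the local-before-distant relapse ordering for one patient.

    The model assumes sequential progression from local to distant relapse.
    When both are recorded at the identical time, 0.1 months is added to
    the distant-relapse time so the intermediate sojourn has positive
    length; a local relapse recorded *after* the distant one is dropped
    (the patient is treated as having had only the distant relapse).
    No-op when the times already satisfy local < distant or either is
    missing.  Idempotent.
    """
    if local is None or distant is None:
        return RelapseTimes(local, distant)
    if local == distant:
        return RelapseTimes(local, distant + 0.1)
    if local > distant:
        return RelapseTimes(None, distant, dropped=True)
    return RelapseTimes(local, distant)


def truncate_covariate(data: MultistateDataset, name: str, cap: float) -> MultistateDataset:
    """Recode values of covariate ``name`` above ``cap`` to ``cap``.

    Returns a new dataset; the input is untouched.  Used to limit the
    leverage of extreme covariate values (e.g., recoding tumor sizes above
    80 mm to 80 mm).
    """
    if name not in data.covariates:
        raise KeyError(f"unknown covariate {name!r}; have {data.covariates}")
    table = data.table.copy()
    col = table[name].astype(float)
    table[name] = np.minimum(col, cap)
    return MultistateDataset(data.graph, table, list(data.covariates))


def expand_covariates(base: pd.DataFrame, graph: TransitionGraph,
                      mapping: CovariateMapping) -> pd.DataFrame:
    """Expand baseline covariates into transition-specific design columns.

    ``base`` has one row per record with a ``trans`` column plus the
    baseline covariate columns named by the mapping.  The result has one
    design column per mapping term: the covariate's value where the row's
    transition is in the term's set, zero elsewhere.  Mapping one column to
    several transitions encodes a shared coefficient.
    """
    mapping.validate(graph)
    if "trans" not in base.columns:
        raise ValueError("base frame needs a 'trans' column")
    out = pd.DataFrame(index=base.index)
    trans = base["trans"].to_numpy()
    for term in mapping.terms:
        if term.covariate not in base.columns:
            raise KeyError(f"mapping references unknown covariate {term.covariate!r}")
        vals = base[term.covariate].to_numpy(dtype=float)
        member = np.isin(trans, list(term.transitions))
        out[term.column] = np.where(member, vals, 0.0)
    return out
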