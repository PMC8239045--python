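"""Domain containers and readers/writers for all pipeline inputs and outputs.

Every downstream module consumes only the types defined here: expression,
mutation and clinical tables are wrapped in light validated containers around
pandas DataFrames, the regulator->targets prior is a ``GeneSetLibrary``, and a
complete inferred network round-trips through a single JSON document
(``NetworkBundle``).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPRESSION_STATES = ("counts", "normalized", "zscored")

#: header/row-id patterns used by orientation auto-detection
SAMPLE_ID_PATTERNS = (
    r"^GSM\d+",
    r"^MMRF[_-]\d+",
    r"^TCGA-",
    r"^(sample|patient)[_-]?\d+$",
    r"^S\d+$",
)
GENE_ID_PATTERNS = (
    r"^ENSG\d{6,}",
    r"^[A-Z0-9]+orf\d+$",
    r"^MIR\d+",
    r"^LINC\d+",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} ids: {dups[:5]}")


class ExpressionMatrix:
    """Gene x sample real-valued matrix with an explicit normalization state.

    Parameters
    ----------
    data : DataFrame, genes in rows, samples in columns.
    state : one of ``counts`` (non-negative, mostly integral),
        ``normalized`` or ``zscored`` (per-gene mean 0, variance 1).
    """

    def __init__(self, data: pd.DataFrame, state: str,
                 flags: Optional[dict] = None) -> None:
        if state not in EXPRESSION_STATES:
            raise ValueError(f"state must be one of {EXPRESSION_STATES}")
        _check_unique(data.index, "gene")
        _check_unique(data.columns, "sample")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise FormatError("expression values must be finite")
        if state == "counts" and (values < 0).any():
            raise FormatError("counts state requires non-negative values")
        if state == "zscored":
            mu = values.mean(axis=1)
            var = values.var(axis=1)
            nonconst = var > 1e-12
            if nonconst.any():
                if (np.abs(mu[nonconst]) > 1e-6).any() or \
                        (np.abs(var[nonconst] - 1.0) > 1e-6).any():
                    raise ValueError(
                        "zscored state requires per-gene mean 0, variance 1")
        self.data = data.astype(float)
        self.state = state
        self.flags = dict(flags or {})

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __eq__(self, other) -> bool:
        return (isinstance(other, ExpressionMatrix)
                and self.state == other.state
                and self.data.equals(other.data))

    def __repr__(self) -> str:
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples, state={self.state})"


@dataclass
class GeneSetLibrary:
    """Mapping regulator id -> set of candidate target gene ids."""

    sets: dict[str, frozenset[str]]
    source_name: str = ""

    def __post_init__(self) -> None:
        cleaned = {}
        for name, genes in self.sets.items():
            genes = frozenset(genes)
            if not genes:
                logger.warning("dropping empty gene set %r", name)
                continue
            cleaned[name] = genes
        self.sets = cleaned

    def __getitem__(self, regulator: str) -> frozenset[str]:
        return self.sets[regulator]

    def __contains__(self, regulator: str) -> bool:
        return regulator in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def regulators(self) -> list[str]:
        return sorted(self.sets)


class MutationMatrix:
    """Binary mutation/aberration x sample matrix; entry 1 marks a carrier."""

    def __init__(self, data: pd.DataFrame) -> None:
        _check_unique(data.index, "mutation")
        _check_unique(data.columns, "sample")
        values = data.to_numpy(dtype=float)
        bad = ~np.isin(values, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"mutation matrix entry not in {{0,1}} at "
                f"row {data.index[i]!r}, column {data.columns[j]!r}: "
                f"{data.iat[i, j]!r}")
        self.data = data.astype(int)

    @property
    def mutation_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def carrier_frequency(self) -> pd.Series:
        return self.data.mean(axis=1)

    def __eq__(self, other) -> bool:
        return isinstance(other, MutationMatrix) and self.data.equals(other.data)


class SurvivalTable:
    """Censored progression-free survival records.

    ``duration`` is in days and must be positive; ``event`` is True when
    progression was observed and False when the record is censored.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"sample_id", "duration", "event"}
        missing = required - set(table.columns)
        if missing:
            raise FormatError(f"missing clinical columns: {sorted(missing)}")
        _check_unique(table["sample_id"], "sample")
        dur = table["duration"].to_numpy(dtype=float)
        if not np.all(np.isfinite(dur)) or (dur <= 0).any():
            bad = table.loc[~(np.isfinite(dur) & (dur > 0)), "sample_id"]
            raise FormatError(
                f"non-positive or non-finite durations for samples "
                f"{bad.tolist()[:5]}")
        tab = table[["sample_id", "duration", "event"]].copy()
        tab["duration"] = dur
        tab["event"] = tab["event"].astype(bool)
        self.table = tab.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def durations(self) -> np.ndarray:
        return self.table["duration"].to_numpy()

    @property
    def events(self) -> np.ndarray:
        return self.table["event"].to_numpy()

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SurvivalTable(keep)

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        return isinstance(other, SurvivalTable) and self.table.equals(other.table)


# ---------------------------------------------------------------------------
# network entities
# ---------------------------------------------------------------------------

@dataclass
class Regulon:
    """A regulator, a signed edge, and >= 5 member genes sharing its binding site."""

    regulon_id: str
    regulator_id: str
    edge_sign: int                      # +1 activator, -1 repressor
    gene_ids: tuple[str, ...]
    regulator_corr: float
    enrichment_p: float = float("nan")
    eigengene: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.edge_sign not in (-1, 1):
            raise ValueError("edge_sign must be +1 or -1")
        self.gene_ids = tuple(self.gene_ids)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Regulon):
            return NotImplemented
        same_eig = (
            (self.eigengene is None and other.eigengene is None)
            or (self.eigengene is not None and other.eigengene is not None
                and self.eigengene.equals(other.eigengene)))
        return (self.regulon_id == other.regulon_id
                and self.regulator_id == other.regulator_id
                and self.edge_sign == other.edge_sign
                and self.gene_ids == other.gene_ids
                and np.isclose(self.regulator_corr, other.regulator_corr,
                               equal_nan=True)
                and np.isclose(self.enrichment_p, other.enrichment_p,
                               equal_nan=True)
                and same_eig)


@dataclass(eq=True)
class Program:
    """A cluster of regulons with similar activity across samples."""

    program_id: str
    regulon_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.regulon_ids = tuple(self.regulon_ids)

    def gene_union(self, regulons: Mapping[str, Regulon]) -> set[str]:
        out: set[str] = set()
        for rid in self.regulon_ids:
            out.update(regulons[rid].gene_ids)
        return out


UNASSIGNED = "UNASSIGNED"


@dataclass
class StateAssignment:
    """Sample -> transcriptional-state mapping plus per-state centroids."""

    assignments: dict[str, str]          # sample -> state id or UNASSIGNED
    centroids: pd.DataFrame              # regulon x state, values in {-1,0,1}

    @property
    def state_ids(self) -> list[str]:
        return list(self.centroids.columns)

    @property
    def assigned_fraction(self) -> float:
        if not self.assignments:
            return 0.0
        n = sum(1 for v in self.assignments.values() if v != UNASSIGNED)
        return n / len(self.assignments)

    def __eq__(self, other) -> bool:
        return (isinstance(other, StateAssignment)
                and self.assignments == other.assignments
                and self.centroids.equals(other.centroids))


@dataclass
class CausalFlow:
    """A mutation -> regulator -> regulon-set causal chain."""

    mutation_id: str
    regulator_id: str
    regulon_ids: tuple[str, ...]
    regulator_effect_sign: int
    regulon_shift_signs: dict[str, int]
    regulator_p: float
    aggregate_p: float
    carrier_frequency: float

    def __post_init__(self) -> None:
        self.regulon_ids = tuple(self.regulon_ids)


@dataclass(eq=True)
class TFEdge:
    """A weighted directed edge between transcription factors."""

    source_tf: str
    target_tf: str
    weight: float

    def __post_init__(self) -> None:
        if self.source_tf == self.target_tf:
            raise ValueError("self edges are not allowed")
        if self.weight == 0:
            raise ValueError("edge weight must be nonzero")


@dataclass
class NetworkBundle:
    """Everything inferred from one cohort, serializable to one JSON document."""

    regulons: list[Regulon] = field(default_factory=list)
    programs: list[Program] = field(default_factory=list)
    states: Optional[StateAssignment] = None
    causal_flows: list[CausalFlow] = field(default_factory=list)
    tf_edges: list[TFEdge] = field(default_factory=list)
    parameters: Optional["Parameters"] = None  # noqa: F821

    SCHEMA_VERSION = 1

    def validate(self) -> None:
        regulon_ids = {r.regulon_id for r in self.regulons}
        regulator_ids = {r.regulator_id for r in self.regulons}
        missing = []
        for p in self.programs:
            missing += [rid for rid in p.regulon_ids if rid not in regulon_ids]
        for f in self.causal_flows:
            missing += [rid for rid in f.regulon_ids if rid not in regulon_ids]
            if f.regulator_id not in regulator_ids:
                missing.append(f.regulator_id)
        if missing:
            raise FormatError(
                f"dangling cross-references: {sorted(set(missing))[:10]}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, NetworkBundle):
            return NotImplemented
        params_eq = (self.parameters is None) == (other.parameters is None)
        if params_eq and self.parameters is not None:
            params_eq = self.parameters.to_dict() == other.parameters.to_dict()
        return (self.regulons == other.regulons
                and self.programs == other.programs
                and self.states == other.states
                and self.causal_flows == other.causal_flows
                and self.tf_edges == other.tf_edges
                and params_eq)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _matches_any(ids: Iterable[str], patterns: Sequence[str]) -> float:
    ids = list(ids)
    if not ids:
        return 0.0
    pats = [re.compile(p, re.IGNORECASE) for p in patterns]
    hits = sum(1 for i in ids if any(p.search(str(i)) for p in pats))
    return hits / len(ids)


def read_expression_matrix(path, orientation_hint: Optional[str] = None,
                           integral_fraction: float = 0.9) -> ExpressionMatrix:
    """Read a delimited gene x sample matrix; orientation is auto-detected.

    Files are genes-in-rows by default; the matrix is transposed when the hint
    says ``samples_by_genes`` or when the row ids look like sample ids (or the
    header looks like gene ids). The state is ``counts`` when all entries are
    non-negative and at least ``integral_fraction`` of them are integral,
    otherwise ``normalized``. Duplicate gene rows are collapsed by their
    arithmetic mean with a logged warning; duplicate sample ids are an error.
    """
    if orientation_hint not in (None, "genes_by_samples", "samples_by_genes"):
        raise ValueError(f"bad orientation_hint {orientation_hint!r}")
    # pandas silently mangles duplicate header ids, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    delim = "\t" if "\t" in header else ","
    header_ids = header.split(delim)[1:]
    if len(header_ids) != len(set(header_ids)):
        dups = sorted({h for h in header_ids if header_ids.count(h) > 1})
        raise FormatError(f"duplicate sample ids in header: {dups[:5]}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:  # pragma: no cover - message shaping
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    nonnum = df.map(lambda v: not isinstance(v, (int, float, np.number)))
    if nonnum.to_numpy().any():
        i, j = np.argwhere(nonnum.to_numpy())[0]
        raise FormatError(
            f"unparseable cell at row {df.index[i]!r}, column "
            f"{df.columns[j]!r}: {df.iat[i, j]!r}")
    if orientation_hint == "samples_by_genes":
        df = df.T
    elif orientation_hint is None:
        row_sampleish = _matches_any(df.index, SAMPLE_ID_PATTERNS)
        col_geneish = _matches_any(df.columns, GENE_ID_PATTERNS)
        if row_sampleish > 0.5 or col_geneish > 0.5:
            logger.info("auto-detected samples-in-rows orientation; transposing")
            df = df.T
    _check_unique(df.columns, "sample")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("collapsing %d duplicated gene ids by mean: %s",
                       len(dups), dups[:5])
        df = df.groupby(level=0, sort=False).mean()
    values = df.to_numpy(dtype=float)
    is_counts = bool(
        values.size
        and (values >= 0).all()
        and np.mean(np.mod(values, 1.0) == 0) >= integral_fraction)
    return ExpressionMatrix(df, state="counts" if is_counts else "normalized")


def read_gene_set_library(path) -> GeneSetLibrary:
    """Read a regulator -> targets prior from GMT or JSON.

    GMT lines are ``name<TAB>description<TAB>gene...``; repeated names are
    merged by union. JSON is ``{"regulator": ["gene", ...], ...}``.
    """
    path = Path(path)
    text = path.read_text()
    sets: dict[str, set[str]] = {}
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        mapping = json.loads(text)
        for name, genes in mapping.items():
            sets.setdefault(name, set()).update(genes)
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields "
                    f"(need >= 3)")
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            sets.setdefault(name, set()).update(genes)
    return GeneSetLibrary({k: frozenset(v) for k, v in sets.items()},
                          source_name=path.name)


def write_gene_set_library(library: GeneSetLibrary, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {k: sorted(v) for k, v in library.sets.items()}
        path.write_text(json.dumps(payload, indent=1))
    else:
        lines = ["\t".join([name, "na", *sorted(genes)])
                 for name, genes in sorted(library.sets.items())]
        path.write_text("\n".join(lines) + "\n")


def read_mutation_matrix(path) -> MutationMatrix:
    """Read a CSV of 0/1 entries, mutations in rows, samples in columns."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return MutationMatrix(df)


_TRUTHY = {"1", "1.0", "true", "t", "yes"}
_FALSY = {"0", "0.0", "false", "f", "no"}


def read_clinical_table(path) -> SurvivalTable:
    """Read a clinical CSV with columns sample_id, pfs_days, pfs_event."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "pfs_days", "pfs_event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing clinical columns: {sorted(missing)}")

    def coerce(v):
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY:
            return False
        raise FormatError(f"cannot parse event flag {v!r}")

    out = pd.DataFrame({
        "sample_id": df["sample_id"].astype(str),
        "duration": df["pfs_days"].astype(float),
        "event": df["pfs_event"].map(coerce),
    })
    return SurvivalTable(out)


# ---------------------------------------------------------------------------
# bundle serialization
# ---------------------------------------------------------------------------

def _series_to_json(s: Optional[pd.Series]):
    if s is None:
        return None
    return {"index": list(map(str, s.index)), "values": [float(v) for v in s]}


def _series_from_json(obj) -> Optional[pd.Series]:
    if obj is None:
        return None
    return pd.Series(obj["values"], index=obj["index"], dtype=float)


def write_network(bundle: NetworkBundle, path) -> None:
    bundle.validate()
    doc = {
        "schema_version": NetworkBundle.SCHEMA_VERSION,
        "regulons": [
            {
                "regulon_id": r.regulon_id,
                "regulator_id": r.regulator_id,
                "edge_sign": r.edge_sign,
                "gene_ids": list(r.gene_ids),
                "regulator_corr": float(r.regulator_corr),
                "enrichment_p": (None if np.isnan(r.enrichment_p)
                                 else float(r.enrichment_p)),
                "eigengene": _series_to_json(r.eigengene),
            }
            for r in bundle.regulons
        ],
        "programs": [
            {"program_id": p.program_id, "regulon_ids": list(p.regulon_ids)}
            for p in bundle.programs
        ],
        "states": None if bundle.states is None else {
            "assignments": bundle.states.assignments,
            "centroid_index": list(bundle.states.centroids.index),
            "centroid_columns": list(bundle.states.centroids.columns),
            "centroid_values": bundle.states.centroids.to_numpy().tolist(),
        },
        "causal_flows": [
            {
                "mutation_id": f.mutation_id,
                "regulator_id": f.regulator_id,
                "regulon_ids": list(f.regulon_ids),
                "regulator_effect_sign": f.regulator_effect_sign,
                "regulon_shift_signs": f.regulon_shift_signs,
                "regulator_p": float(f.regulator_p),
                "aggregate_p": float(f.aggregate_p),
                "carrier_frequency": float(f.carrier_frequency),
            }
            for f in bundle.causal_flows
        ],
        "tf_edges": [
            {"source_tf": e.source_tf, "target_tf": e.target_tf,
             "weight": float(e.weight)}
            for e in bundle.tf_edges
        ],
        "parameters": (None if bundle.parameters is None
                       else bundle.parameters.to_dict()),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_network(path) -> NetworkBundle:
    from .params import Parameters

    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != NetworkBundle.SCHEMA_VERSION:
        raise FormatError(f"unsupported schema version {version!r}")
    regulons = [
        Regulon(
            regulon_id=r["regulon_id"],
            regulator_id=r["regulator_id"],
            edge_sign=int(r["edge_sign"]),
            gene_ids=tuple(r["gene_ids"]),
            regulator_corr=float(r["regulator_corr"]),
            enrichment_p=(float("nan") if r.get("enrichment_p") is None
                          else float(r["enrichment_p"])),
            eigengene=_series_from_json(r.get("eigengene")),
        )
        for r in doc.get("regulons", [])
    ]
    programs = [Program(p["program_id"], tuple(p["regulon_ids"]))
                for p in doc.get("programs", [])]
    states = None
    if doc.get("states") is not None:
        s = doc["states"]
        centroids = pd.DataFrame(np.asarray(s["centroid_values"], dtype=int),
                                 index=s["centroid_index"],
                                 columns=s["centroid_columns"])
        states = StateAssignment(dict(s["assignments"]), centroids)
    flows = [
        CausalFlow(
            mutation_id=f["mutation_id"],
            regulator_id=f["regulator_id"],
            regulon_ids=tuple(f["regulon_ids"]),
            regulator_effect_sign=int(f["regulator_effect_sign"]),
            regulon_shift_signs={k: int(v)
                                 for k, v in f["regulon_shift_signs"].items()},
            regulator_p=float(f["regulator_p"]),
            aggregate_p=float(f["aggregate_p"]),
            carrier_frequency=float(f["carrier_frequency"]),
        )
        for f in doc.get("causal_flows", [])
    ]
    edges = [TFEdge(e["source_tf"], e["target_tf"], float(e["weight"]))
             for e in doc.get("tf_edges", [])]
    parameters = (None if doc.get("parameters") is None
                  else Parameters.from_dict(doc["parameters"]))
    bundle = NetworkBundle(regulons=regulons, programs=programs, states=states,
                           causal_flows=flows, tf_edges=edges,
                           parameters=parameters)
    bundle.validate()
    return bundle


def roundtrip_network(bundle: NetworkBundle, path) -> NetworkBundle:
    """Write then re-read a bundle; the result compares equal field-by-field."""
    write_network(bundle, path)
    return read_network(path)
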