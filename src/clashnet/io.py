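"""TSV/JSON/YAML readers and writers for every artifact.

Formats (all plain text, tab-separated):

* association matrix — header row ``disease<TAB>feature ids...``, one row
  per disease;
* disease network — 3-column edge list ``a<TAB>b<TAB>weight`` (id-
  lexicographically smaller id first, one undirected edge per line) plus a
  companion node-list file preserving the full node ordering, including
  isolated nodes;
* pair tables (external evidence / reference standard) — 2 or 3 columns
  ``a<TAB>b[<TAB>strength]``;
* score vectors — 2 columns ``disease<TAB>score``;
* run results — edge list + node list + a JSON log.

Writers emit floats with ``repr`` (shortest round-tripping form), so a
write/read cycle reproduces objects exactly and canonical files round-trip
byte-identically. Malformed lines raise :class:`InvalidInputError` naming
the offending line number.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ClashConfig, ClashResult, ExternalEvidence
from .errors import InvalidInputError
from .evaluate import ReferenceStandard, canonical_pair
from .network import AssociationMatrix, DiseaseNetwork
from .ssl import SSLConfig

logger = logging.getLogger("clashnet")

__all__ = [
    "read_association_tsv",
    "write_association_tsv",
    "read_edge_list",
    "write_edge_list",
    "read_pairs",
    "read_evidence",
    "read_standard",
    "write_pairs",
    "write_scores",
    "write_result",
    "RunConfig",
]


def read_association_tsv(path) -> AssociationMatrix:
    """Read a disease × feature table (header = feature ids, first column
    = disease ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed layout / unreadable file
        raise InvalidInputError(f"{path}: cannot parse association table: {exc}") from exc
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for lineno, (_, row) in enumerate(df.iterrows(), start=2):
            for cell in row:
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise InvalidInputError(
                        f"{path}:{lineno}: non-numeric cell {cell!r}"
                    ) from None
        values = values.astype(float)
    return AssociationMatrix(tuple(map(str, df.index)), tuple(map(str, df.columns)), values)


def write_association_tsv(assoc: AssociationMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("disease\t" + "\t".join(assoc.features) + "\n")
        for d, row in zip(assoc.diseases, assoc.values):
            fh.write(d + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _parse_pair_lines(path, max_cols: int):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not 2 <= len(parts) <= max_cols:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 2–{max_cols} tab-separated columns, "
                    f"got {len(parts)}"
                )
            a, b = parts[0], parts[1]
            if a == b:
                raise InvalidInputError(f"{path}:{lineno}: self-pair {a!r}")
            strength = None
            if len(parts) == 3:
                try:
                    strength = float(parts[2])
                except ValueError:
                    raise InvalidInputError(
                        f"{path}:{lineno}: non-numeric value {parts[2]!r}"
                    ) from None
            rows.append((lineno, canonical_pair(a, b), strength))
    return rows


def read_edge_list(path, nodes_path=None) -> DiseaseNetwork:
    """Read a 3-column weighted edge list; ``nodes_path`` (one id per
    line) restores the full node ordering including isolated nodes."""
    rows = _parse_pair_lines(path, max_cols=3)
    edges: dict[tuple[str, str], float] = {}
    for lineno, pair, w in rows:
        if w is None:
            raise InvalidInputError(f"{path}:{lineno}: edge list needs a weight column")
        if pair in edges:
            if edges[pair] != w:
                raise InvalidInputError(
                    f"{path}:{lineno}: pair {pair} listed twice with conflicting weights"
                )
            logger.warning("%s:%d: duplicate edge %s, deduplicated", path, lineno, pair)
            continue
        if not 0 < w <= 1:
            raise InvalidInputError(f"{path}:{lineno}: weight {w} outside (0, 1]")
        edges[pair] = w
    if nodes_path is not None:
        nodes = tuple(
            line.strip() for line in open(nodes_path) if line.strip()
        )
    else:
        nodes = tuple(sorted({v for pair in edges for v in pair}))
    if len(nodes) < 2:
        raise InvalidInputError(f"{path}: a network needs at least 2 nodes")
    W = np.zeros((len(nodes), len(nodes)))
    idx = {v: i for i, v in enumerate(nodes)}
    for (a, b), w in edges.items():
        if a not in idx or b not in idx:
            raise InvalidInputError(f"{path}: edge node not in node list: {(a, b)}")
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
    return DiseaseNetwork(nodes, W)


def write_edge_list(net: DiseaseNetwork, path, nodes_path=None) -> None:
    with open(path, "w") as fh:
        for a, b, w in net.edges():
            fh.write(f"{a}\t{b}\t{w!r}\n")
    if nodes_path is not None:
        with open(nodes_path, "w") as fh:
            for v in net.nodes:
                fh.write(v + "\n")


def read_pairs(path) -> dict[tuple[str, str], float | None]:
    """Read a 2/3-column pair table into a canonical pair -> strength map.

    Duplicate pairs with identical strength are deduplicated (warning);
    conflicting strengths are an error.
    """
    out: dict[tuple[str, str], float | None] = {}
    for lineno, pair, strength in _parse_pair_lines(path, max_cols=3):
        if pair in out:
            if out[pair] != strength:
                raise InvalidInputError(
                    f"{path}:{lineno}: pair {pair} listed twice with conflicting values"
                )
            logger.warning("%s:%d: duplicate pair %s, deduplicated", path, lineno, pair)
            continue
        out[pair] = strength
    return out


def read_evidence(path) -> ExternalEvidence:
    pairs = read_pairs(path)
    return ExternalEvidence({p: (1.0 if s is None else s) for p, s in pairs.items()})


def read_standard(path) -> ReferenceStandard:
    return ReferenceStandard(frozenset(read_pairs(path)))


def write_pairs(pairs, path) -> None:
    """Write evidence/standard pairs; mapping values (if any) become the
    third column."""
    items = pairs.pairs.items() if isinstance(pairs, ExternalEvidence) else None
    with open(path, "w") as fh:
        if items is not None:
            for (a, b), s in sorted(items):
                fh.write(f"{a}\t{b}\t{s!r}\n")
        else:
            seq = pairs.positives if isinstance(pairs, ReferenceStandard) else pairs
            for a, b in sorted(seq):
                fh.write(f"{a}\t{b}\n")


def write_scores(nodes, scores, path) -> None:
    with open(path, "w") as fh:
        for v, s in zip(nodes, scores):
            fh.write(f"{v}\t{float(s)!r}\n")


def write_result(result: ClashResult, out_dir) -> None:
    """Serialize a run: complemented edge list + node list + JSON log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_edge_list(result.network, out / "complemented_edges.tsv", out / "nodes.tsv")
    (out / "clash_result.json").write_text(result.to_json(indent=2) + "\n")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated top-level configuration (YAML/JSON ``ssl:`` + ``clash:``
    sections plus a global seed). Unknown keys are rejected."""

    ssl: SSLConfig = dataclasses.field(default_factory=SSLConfig)
    clash: ClashConfig = dataclasses.field(default_factory=ClashConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise InvalidInputError("config must be a mapping")
        known = {"ssl", "clash", "seed"}
        unknown = set(data) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")

        def build(cfg_cls, section):
            section = data.get(section) or {}
            fields = {f.name for f in dataclasses.fields(cfg_cls)}
            bad = set(section) - fields
            if bad:
                raise InvalidInputError(f"unknown config keys: {sorted(bad)}")
            try:
                return cfg_cls(**section)
            except TypeError as exc:
                raise InvalidInputError(str(exc)) from exc

        return cls(
            ssl=build(SSLConfig, "ssl"),
            clash=build(ClashConfig, "clash"),
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise InvalidInputError(f"{path}: cannot parse YAML: {exc}") from exc
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return {
            "ssl": dataclasses.asdict(self.ssl),
            "clash": dataclasses.asdict(self.clash),
            "seed": self.seed,
        }


def write_manifest(out_dir, config: RunConfig, extra: dict | None = None) -> None:
    """Record everything needed to reproduce a CLI run exactly."""
    from . import __version__

    manifest = {"version": __version__, "config": config.to_dict()}
    if extra:
        manifest.update(extra)
    Path(out_dir, "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
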