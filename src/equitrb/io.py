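"""Readers and writers for the formats the toolkit touches.

Reads come in as FASTA or FASTQ (Biopython-parsed; qualities are ignored
downstream).  Germline sets use a small FASTA dialect whose header packs
``NAME|TYPE|CLUSTER|FUNCTIONALITY|SUBGROUP`` (empty fields where not
applicable), with recombination signals in a sidecar TSV (name, end,
heptamer, spacer, nonamer) and V-REGION offsets in a second sidecar.
Run configuration is strict YAML: unknown keys are rejected so a config
file always describes exactly the run that will happen.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from .germline import (
    Functionality,
    GeneType,
    GermlineGene,
    GermlineSet,
    Orientation,
    RecombinationSignal,
)
from .pipeline import PipelineConfig
from .simulate import MaxTrim, SimConfig, SyntheticRead, TrimP

__all__ = [
    "read_sequences",
    "write_sequences",
    "write_germline",
    "read_germline",
    "RunConfig",
    "load_config",
]


def read_sequences(path, fmt: str | None = None) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ into (id, uppercase sequence) pairs.

    The format is taken from the extension when not given.  Order is
    preserved; malformed records raise with the offending record named.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "fastq" if suffix in (".fastq", ".fq") else "fasta"
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    records = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            records.append((rec.id, str(rec.seq).upper()))
    except ValueError as exc:
        raise ValueError(
            f"{path}: malformed {fmt} after record "
            f"{records[-1][0] if records else '<start>'}: {exc}") from exc
    return records


def write_sequences(reads, path, fmt: str | None = None) -> None:
    """Write reads (``SyntheticRead`` or (id, seq) pairs) as FASTA/FASTQ.

    FASTQ qualities are constant 'I' (the simulator does not model
    quality)."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "fastq" if suffix in (".fastq", ".fq") else "fasta"
    with open(path, "w") as fh:
        for r in reads:
            rid, seq = (r.read_id, r.seq) if isinstance(r, SyntheticRead) else (r[0], r[1])
            if fmt == "fasta":
                fh.write(f">{rid}\n{seq}\n")
            else:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# germline FASTA dialect
# ---------------------------------------------------------------------------

def write_germline(germline: GermlineSet, directory) -> None:
    """Write a germline set: genes.fasta (header
    NAME|TYPE|CLUSTER|FUNCTIONALITY|SUBGROUP), rs.tsv with the
    recombination signals, and v_spans.tsv with V-REGION offsets."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "genes.fasta", "w") as fh:
        for g in germline:
            cluster = "" if g.cluster_id is None else str(g.cluster_id)
            subgroup = g.subgroup or ""
            header = f"{g.name}|{g.gene_type.value}|{cluster}|{g.functionality.value}|{subgroup}"
            if g.orientation is Orientation.INVERTED:
                header += "|inverted"
            fh.write(f">{header}\n{g.coding_nt}\n")
    with open(directory / "rs.tsv", "w") as fh:
        fh.write("name\tend\theptamer\tspacer\tnonamer\n")
        for g in germline:
            for end, rs in (("5prime", g.rs_5prime), ("3prime", g.rs_3prime)):
                if rs is not None:
                    fh.write(f"{g.name}\t{end}\t{rs.heptamer}\t{rs.spacer}\t{rs.nonamer}\n")
    with open(directory / "v_spans.tsv", "w") as fh:
        fh.write("name\tv_region_start\n")
        for g in germline:
            if g.gene_type is GeneType.V and g.v_region_start is not None:
                fh.write(f"{g.name}\t{g.v_region_start}\n")


def read_germline(directory) -> GermlineSet:
    """Read a germline set written by :func:`write_germline`."""
    directory = Path(directory)
    rs_map: dict[tuple[str, str], RecombinationSignal] = {}
    rs_path = directory / "rs.tsv"
    if rs_path.exists():
        with open(rs_path) as fh:
            header = fh.readline()
            for ln, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 5:
                    raise ValueError(f"{rs_path}:{ln}: expected 5 fields")
                name, end, hept, spacer, nona = parts
                rs_map[(name, end)] = RecombinationSignal(hept, spacer, nona)
    spans: dict[str, int] = {}
    span_path = directory / "v_spans.tsv"
    if span_path.exists():
        with open(span_path) as fh:
            fh.readline()
            for line in fh:
                name, start = line.rstrip("\n").split("\t")
                spans[name] = int(start)
    genes = []
    for rec in SeqIO.parse(str(directory / "genes.fasta"), "fasta"):
        parts = rec.description.split("|")
        if len(parts) < 5:
            raise ValueError(f"{rec.id}: germline header needs 5 pipe fields")
        name, gtype, cluster, functionality, subgroup = parts[:5]
        inverted = len(parts) > 5 and parts[5] == "inverted"
        genes.append(GermlineGene(
            name=name, gene_type=GeneType(gtype), coding_nt=str(rec.seq).upper(),
            rs_5prime=rs_map.get((name, "5prime")),
            rs_3prime=rs_map.get((name, "3prime")),
            cluster_id=int(cluster) if cluster else None,
            subgroup=subgroup or None,
            functionality=Functionality(functionality),
            orientation=Orientation.INVERTED if inverted else Orientation.FORWARD,
            v_region_start=spans.get(name),
        ))
    return GermlineSet(genes)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Merged simulator + pipeline configuration with run-level settings."""

    sim: SimConfig = field(default_factory=SimConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    out_dir: str = "run"
    log_level: str = "INFO"
    seed: int = 0


_NESTED = {"trim_geometric_p": TrimP, "max_trim": MaxTrim}


def _build_dataclass(cls, data: dict, context: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ValueError(f"unknown {context} keys: {', '.join(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            value = _build_dataclass(_NESTED[key], value, f"{context}.{key}")
        elif key == "n_insert_length_dist" and isinstance(value, dict):
            value = {int(k): float(v) for k, v in value.items()}
        elif key in ("d_lengths", "j_per_cluster", "class_mix", "d_usage",
                     "cdr3_codon_range") and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a strict YAML run configuration.

    Absent keys fall back to defaults (an empty file yields the default
    configuration, i.e. probe identity 98, 120-nt windows, 6-nt D matches);
    unknown keys raise with the offenders listed.  ``overrides`` (same
    nesting) are applied on top.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data = loaded
    if overrides:
        for key, value in overrides.items():
            if isinstance(value, dict) and isinstance(data.get(key), dict):
                data[key].update(value)
            else:
                data[key] = value
    top_unknown = sorted(set(data) - {"sim", "pipeline", "out_dir",
                                      "log_level", "seed"})
    if top_unknown:
        raise ValueError(f"unknown config keys: {', '.join(top_unknown)}")
    sim = _build_dataclass(SimConfig, dict(data.get("sim") or {}), "sim")
    pipe = _build_dataclass(PipelineConfig, dict(data.get("pipeline") or {}),
                            "pipeline")
    cfg = RunConfig(sim=sim, pipeline=pipe,
                    out_dir=str(data.get("out_dir", "run")),
                    log_level=str(data.get("log_level", "INFO")),
                    seed=int(data.get("seed", 0)))
    if "seed" in data:
        cfg.sim.seed = cfg.seed
    return cfg
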