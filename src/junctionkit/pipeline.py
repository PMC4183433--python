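"""Orchestration: simulate -> call -> origin-search -> stats as one
configured, logged, reproducible run; plus the bundled junction-table
fixture transcribed from the published 31-row table (9 WT, 21
WT+NU7026, 1 KO).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .errors import FixtureIntegrityError, InvalidArgumentError
from .insertion_origin import OriginConfig, find_origin, classify_templated, origin_distance
from .junction_caller import CallerConfig, JunctionCall, call_junction, to_table_row
from .sequences import Reference, load_references, write_fasta
from .stats import GroupSummary, compare_groups, insertion_fraction
from .synthetic_data import (
    JoinConfig,
    generate_switch_region,
    simulate_dataset,
    truth_row,
    write_reads_fasta,
    write_truth_tsv,
    TRUTH_COLUMNS,
)

_FIXTURE_NAME = "table1_junctions.tsv"
_FIXTURE_SHA256 = "d337c109c22a53df1b104e4416d25fc09cba751bb9dc466f6a6c4f2fc6dba89b"

CALL_COLUMNS = [
    "read_id", "group", "junction_class", "mh_len", "mh_seq", "insertion_seq",
    "insertion_len", "donor_interval", "donor_flank", "acceptor_flank",
    "acceptor_interval", "ambiguity_interval", "mutations", "homology",
    "low_confidence",
]


@dataclass(frozen=True)
class Table1Fixture:
    """One transcribed row: 30-nt flanks (mutations lower-case), the
    insertion (dashes mark base deletions relative to its origin), the
    flank intervals, and an optional origin annotation."""

    group: str
    donor_interval: tuple[int, int]
    donor_flank: str
    insertion: str
    acceptor_flank: str
    acceptor_interval: tuple[int, int]
    homology: str = ""

    @property
    def insertion_letters(self) -> str:
        """Insertion with deletion dashes stripped, uppercased."""
        return self.insertion.replace("-", "").upper()

    @property
    def read(self) -> str:
        """The junction read rebuilt from the printed row."""
        return (self.donor_flank + self.insertion_letters + self.acceptor_flank).upper()

    def donor_reference(self) -> Reference:
        return Reference(id=f"donor_{self.donor_interval[0]}", sequence=self.donor_flank, role="donor")

    def acceptor_reference(self) -> Reference:
        return Reference(
            id=f"acceptor_{self.acceptor_interval[0]}", sequence=self.acceptor_flank, role="acceptor"
        )


def _parse_interval(text: str) -> tuple[int, int]:
    s, e = text.split(":")
    return int(s), int(e)


def load_table1_fixture() -> list[Table1Fixture]:
    """Load and checksum-verify the bundled 31-row junction fixture."""
    raw = resources.files("junctionkit").joinpath("data", _FIXTURE_NAME).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureIntegrityError(
            f"bundled fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    rows: list[Table1Fixture] = []
    lines = raw.decode().splitlines()
    for line in lines[1:]:
        parts = line.split("\t")
        group, d_iv, d_fl, ins, a_fl, a_iv = parts[:6]
        homology = parts[6] if len(parts) > 6 else ""
        fx = Table1Fixture(
            group=group,
            donor_interval=_parse_interval(d_iv),
            donor_flank=d_fl,
            insertion=ins,
            acceptor_flank=a_fl,
            acceptor_interval=_parse_interval(a_iv),
            homology=homology,
        )
        if len(fx.donor_flank) != 30 or len(fx.acceptor_flank) != 30:
            raise FixtureIntegrityError(f"fixture flank not 30 nt in group {group}")
        for iv in (fx.donor_interval, fx.acceptor_interval):
            if iv[1] - iv[0] + 1 != 30:
                raise FixtureIntegrityError(f"fixture interval {iv} does not span 30 nt")
        rows.append(fx)
    counts = {g: sum(1 for r in rows if r.group == g) for g in ("WT", "WT+NU7026", "KO")}
    if counts != {"WT": 9, "WT+NU7026": 21, "KO": 1}:
        raise FixtureIntegrityError(f"unexpected fixture group counts: {counts}")
    return rows


@dataclass
class RunConfig:
    """One configured run.  Exactly one input mode is active:

    * ``mode="fixture"``   — the bundled printed-table rows;
    * ``mode="simulate"``  — the seeded simulator (``simulation`` block);
    * ``mode="reads"``     — user FASTA reads plus donor/acceptor refs.
    """

    mode: str = "fixture"
    out_dir: str = "results"
    seed: int = 0
    n_total_per_group: int = 100
    reads_path: str | None = None
    donor_path: str | None = None
    acceptor_path: str | None = None
    simulation: dict = field(default_factory=dict)
    caller: dict = field(default_factory=dict)
    origin: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("fixture", "simulate", "reads"):
            raise InvalidArgumentError(f"unknown run mode {self.mode!r}")
        if self.mode == "reads" and not (self.reads_path and self.donor_path and self.acceptor_path):
            raise InvalidArgumentError("reads mode requires reads/donor/acceptor paths")
        if self.mode == "simulate" and self.reads_path:
            raise InvalidArgumentError("give either input paths or a simulation block, not both")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _call_record(
    read_id: str,
    group: str,
    call: JunctionCall,
    donor: Reference,
    acceptor: Reference,
    read: str,
    cfg: CallerConfig,
    homology: str = "",
) -> list[str]:
    row = to_table_row(call, donor, acceptor, read, cfg, homology=homology)
    amb = (
        f"{call.mh_ambiguity_read_interval[0]}:{call.mh_ambiguity_read_interval[1]}"
        if call.mh_ambiguity_read_interval
        else ""
    )
    muts = ";".join(
        f"{m.side}:{m.ref_pos}:{m.ref_base}>{m.read_base}" for m in call.flank_mutations
    )
    return [
        read_id, group, call.junction_class, str(call.mh_len), call.mh_seq,
        call.insertion_seq, str(len(call.insertion_seq)), row.donor_interval,
        row.donor_flank, row.acceptor_flank, row.acceptor_interval, amb, muts,
        homology, str(int(call.low_confidence)),
    ]


@dataclass
class RunResult:
    call_rows: list[list[str]]
    summaries: list[GroupSummary]
    comparisons: dict[tuple[str, str], float]
    run_log: dict
    truth_rows: list[list[str]] = field(default_factory=list)
    origin_rows: list[list[str]] = field(default_factory=list)


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the configured stages in order; rerunning with the same
    config and seed reproduces identical outputs."""
    caller_cfg = CallerConfig(**cfg.caller)
    origin_cfg = OriginConfig(**cfg.origin)
    log: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "config": {
            "caller": asdict(caller_cfg),
            "origin": asdict(origin_cfg),
            "simulation": dict(cfg.simulation),
            "n_total_per_group": cfg.n_total_per_group,
        },
        "stages": [],
    }

    call_rows: list[list[str]] = []
    truth_rows: list[list[str]] = []
    origin_rows: list[list[str]] = []
    group_lengths: dict[str, list[int]] = {}

    if cfg.mode == "fixture":
        rows = load_table1_fixture()
        log["stages"].append({"stage": "fixture", "rows": len(rows)})
        for i, fx in enumerate(rows):
            donor = fx.donor_reference()
            acceptor = fx.acceptor_reference()
            call = call_junction(fx.read, donor, acceptor, caller_cfg, read_id=f"row{i:02d}")
            call_rows.append(
                _call_record(f"row{i:02d}", fx.group, call, donor, acceptor, fx.read,
                             caller_cfg, homology=fx.homology)
            )
            group_lengths.setdefault(fx.group, []).append(len(call.insertion_seq))
        log["stages"].append({"stage": "call", "reads": len(rows)})
    elif cfg.mode == "simulate":
        sim = dict(cfg.simulation)
        length = int(sim.pop("region_length", 3000))
        units = tuple(sim.pop("repeat_units", ("GAGCT", "GGGGT")))
        noise = float(sim.pop("region_noise", 0.02))
        n = int(sim.pop("n_per_group", cfg.n_total_per_group))
        mixture = dict(sim.pop("mixture", {"CNHEJ": 0.6, "MMEJ": 0.2, "SDEJ": 0.2}))
        join_cfg = JoinConfig(seed=cfg.seed, **sim)
        donor_region = generate_switch_region(length, units, seed=cfg.seed, noise=noise, region_id="donor_sim")
        acceptor_region = generate_switch_region(length, units, seed=cfg.seed + 1, noise=noise, region_id="acceptor_sim")
        donor = donor_region.as_reference("donor")
        acceptor = acceptor_region.as_reference("acceptor")
        reads, counts = simulate_dataset(n, mixture, donor_region, acceptor_region, join_cfg)
        log["stages"].append({"stage": "simulate", "reads": len(reads), "mechanism_counts": counts})
        for read in reads:
            call = call_junction(read.sequence, donor, acceptor, caller_cfg, read_id=read.read_id)
            homology = ""
            if call.insertion_seq and len(call.insertion_seq) >= origin_cfg.min_templated_len:
                hits = find_origin(call.insertion_seq, [donor, acceptor], origin_cfg)
                verdict = classify_templated(hits, call.insertion_seq, origin_cfg)
                if hits:
                    top = hits[0]
                    breakpoints = {
                        donor.id: call.donor_aln.ref_end,
                        acceptor.id: call.acceptor_aln.ref_start,
                    }
                    dist = origin_distance(top, breakpoints)
                    homology = f"{top.ref_id}{top.start}:{top.end}"
                    origin_rows.append([
                        read.read_id, call.insertion_seq, top.ref_id, str(top.start),
                        str(top.end), top.strand, str(top.score), f"{top.identity:.4f}",
                        str(top.gap_count), str(dist), str(int(top.unique)), verdict,
                    ])
            call_rows.append(
                _call_record(read.read_id, "sim", call, donor, acceptor, read.sequence,
                             caller_cfg, homology=homology)
            )
            group_lengths.setdefault("sim", []).append(len(call.insertion_seq))
            truth_rows.append(truth_row(read))
        log["stages"].append({"stage": "call", "reads": len(reads)})
        log["stages"].append({"stage": "origin", "insertions_searched": len(origin_rows)})
    else:  # reads mode
        from Bio import SeqIO

        donor = load_references([cfg.donor_path])[0]
        acceptor = load_references([cfg.donor_path, cfg.acceptor_path])[1]
        records = list(SeqIO.parse(cfg.reads_path, "fasta"))
        log["stages"].append({"stage": "load", "reads": len(records)})
        for rec in records:
            call = call_junction(str(rec.seq), donor, acceptor, caller_cfg, read_id=rec.id)
            call_rows.append(
                _call_record(rec.id, "all", call, donor, acceptor, str(rec.seq).upper(), caller_cfg)
            )
            group_lengths.setdefault("all", []).append(len(call.insertion_seq))
        log["stages"].append({"stage": "call", "reads": len(records)})

    summaries = [
        insertion_fraction(
            lengths,
            max(cfg.n_total_per_group, len(lengths)),
            group=g,
            min_insertion_len=caller_cfg.insertion_report_min,
        )
        for g, lengths in sorted(group_lengths.items())
    ]
    comparisons = compare_groups(summaries) if len(summaries) >= 2 else {}
    log["stages"].append({"stage": "stats", "groups": [s.group for s in summaries]})
    return RunResult(
        call_rows=call_rows,
        summaries=summaries,
        comparisons=comparisons,
        run_log=log,
        truth_rows=truth_rows,
        origin_rows=origin_rows,
    )


ORIGIN_COLUMNS = [
    "read_id", "insertion_seq", "ref_id", "start", "end", "strand", "score",
    "identity", "gap_count", "distance", "unique", "verdict",
]


def write_report(result: RunResult, out_dir: str | Path) -> list[Path]:
    """Write the per-stage TSVs and a JSON summary with stable ordering;
    repeated writes are byte-identical."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InvalidArgumentError(f"cannot create output directory {out}: {exc}") from exc
    written: list[Path] = []

    calls_path = out / "junction_calls.tsv"
    with open(calls_path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for row in result.call_rows:
            fh.write("\t".join(row) + "\n")
    written.append(calls_path)

    if result.truth_rows:
        truth_path = out / "truth.tsv"
        with open(truth_path, "w") as fh:
            fh.write("\t".join(TRUTH_COLUMNS) + "\n")
            for row in result.truth_rows:
                fh.write("\t".join(row) + "\n")
        written.append(truth_path)

    if result.origin_rows:
        origin_path = out / "origins.tsv"
        with open(origin_path, "w") as fh:
            fh.write("\t".join(ORIGIN_COLUMNS) + "\n")
            for row in result.origin_rows:
                fh.write("\t".join(row) + "\n")
        written.append(origin_path)

    summary = {
        "groups": [
            {
                "group": s.group,
                "n_total": s.n_total,
                "n_insertions_gt1": s.n_insertions_gt1,
                "fraction": s.fraction,
                "ci95": [s.ci_low, s.ci_high],
            }
            for s in result.summaries
        ],
        "fisher_comparisons": {
            f"{a} vs {b}": p for (a, b), p in sorted(result.comparisons.items())
        },
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(summary_path)

    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(result.run_log, indent=2, sort_keys=True) + "\n")
    written.append(log_path)
    return written
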