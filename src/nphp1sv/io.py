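"""Standard-format I/O: headered TSV dialects, FASTA, BED, and the pipeline
configuration file.

All TSV writers emit a provenance comment block (lines starting with '#':
config hash, seed, package version) followed by a header row; readers skip
comments and reject malformed rows with their line numbers.  Outputs contain
no timestamps, so identical config + seed reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .dosage import RegionDosage
from .locus import GenomeInterval, Haplotype, LocusArchitecture
from .rmap import Rmap
from .simulate import FosmidESP, SimParams

__all__ = [
    "PipelineConfig",
    "load_config",
    "dump_config",
    "provenance_lines",
    "write_tsv",
    "read_tsv",
    "write_esps",
    "read_esps",
    "write_rmaps",
    "read_rmaps",
    "write_dosage",
    "read_dosage",
    "write_fasta",
    "read_fasta",
    "haplotype_to_bed",
]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run needs; round-trips through YAML unchanged."""

    seed: int = 0
    outdir: str = "nphp1sv_out"
    truth_genotype: tuple = ("H2", "H2")
    populations: dict = field(default_factory=lambda: {
        # haplotype frequencies chosen so the expected diploid copy-number
        # distribution echoes the observed population polymorphism
        "YRI": {"H1": 0.25, "H2": 0.55, "H5": 0.10, "H7": 0.10},
        "CEU": {"H1": 0.10, "H2": 0.70, "H5": 0.10, "H7": 0.10},
        "CHB+JPT": {"H1": 0.15, "H2": 0.65, "H5": 0.10, "H7": 0.10},
    })
    n_individuals: int = 50
    n_clones: int = 200
    n_molecules: int = 12
    sim: dict = field(default_factory=dict)  # SimParams overrides
    insert_min: int = 32_000
    insert_max: int = 48_000
    min_mapq: int = 20
    min_support: int = 1
    rmap_sigma_rel: float = 0.05
    rmap_c_cut: float = 3.0
    rmap_delta: int = 3
    rmap_margin: float = 5.0
    rmap_min_fragment_kb: float = 0.8
    cn_ref: int = 4
    lcr_k: int = 31
    lcr_min_block: int = 10_000
    lcr_min_identity: float = 0.9
    motif_threshold: float = 0.85

    def sim_params(self) -> SimParams:
        return SimParams(seed=self.seed, **self.sim)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["truth_genotype"] = list(self.truth_genotype)
        return d

    def sha256(self) -> str:
        """Hash of the scientific parameters (output location excluded, so
        identical runs in different directories share a provenance hash)."""
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "sim" in raw and raw["sim"]:
        sim_known = {f.name for f in dataclasses.fields(SimParams)} - {"seed"}
        bad = set(raw["sim"]) - sim_known
        if bad:
            raise ValueError(f"unknown sim parameter keys: {sorted(bad)}")
    if "truth_genotype" in raw:
        raw = dict(raw, truth_genotype=tuple(raw["truth_genotype"]))
    return PipelineConfig(**raw)


def dump_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


# --------------------------------------------------------------------------
# TSV plumbing
# --------------------------------------------------------------------------

def provenance_lines(cfg: PipelineConfig | None = None, seed: int | None = None):
    lines = [f"# nphp1sv_version={__version__}"]
    if cfg is not None:
        lines.append(f"# config_sha256={cfg.sha256()}")
    if seed is not None:
        lines.append(f"# seed={seed}")
    return lines


def write_tsv(path, df: pd.DataFrame, cfg: PipelineConfig | None = None,
              seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(cfg, seed):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path, required_columns=None) -> pd.DataFrame:
    # keep_default_na=False: 'NA' is a legitimate categorical value (e.g. the
    # side of a concordant clone), not a missing cell
    df = pd.read_csv(path, sep="\t", comment="#",
                     keep_default_na=False, na_values=[""])
    if required_columns:
        missing = set(required_columns) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for col in required_columns:
            bad = df.index[df[col].isna()]
            if len(bad):
                # +2: header line and 1-based numbering (comments excluded)
                raise ValueError(
                    f"{path}: malformed row at data line {int(bad[0]) + 2} "
                    f"(missing {col})"
                )
    return df


# --------------------------------------------------------------------------
# Concrete formats
# --------------------------------------------------------------------------

ESP_COLUMNS = ["clone_id", "chrom", "pos1", "strand1", "pos2", "strand2", "mapq"]


def write_esps(path, esps, cfg=None, seed=None) -> None:
    df = pd.DataFrame([
        (e.clone_id, e.chrom, e.pos1, e.strand1, e.pos2, e.strand2, e.mapq)
        for e in esps
    ], columns=ESP_COLUMNS)
    write_tsv(path, df, cfg, seed)


def read_esps(path) -> list:
    df = read_tsv(path, ESP_COLUMNS)
    return [
        FosmidESP(str(r.clone_id), str(r.chrom), int(r.pos1), str(r.strand1),
                  int(r.pos2), str(r.strand2), int(r.mapq))
        for r in df.itertuples(index=False)
    ]


RMAP_COLUMNS = ["map_id", "enzyme", "fragments_kb"]


def write_rmaps(path, rmaps, cfg=None, seed=None) -> None:
    df = pd.DataFrame([
        (r.map_id, r.enzyme, ",".join(f"{f:.4f}" for f in r.fragments))
        for r in rmaps
    ], columns=RMAP_COLUMNS)
    write_tsv(path, df, cfg, seed)


def read_rmaps(path) -> list:
    df = read_tsv(path, RMAP_COLUMNS)
    out = []
    for i, r in enumerate(df.itertuples(index=False)):
        try:
            frags = tuple(float(x) for x in str(r.fragments_kb).split(","))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed fragment list at data line "
                             f"{i + 2}") from exc
        out.append(Rmap(str(r.map_id), str(r.enzyme), frags))
    return out


DOSAGE_COLUMNS = ["probe_id", "chrom", "start", "end", "value", "kind"]


def write_dosage(path, d: RegionDosage, cfg=None, seed=None, width: int = 1) -> None:
    df = pd.DataFrame({
        "probe_id": [f"m{i:06d}" for i in range(len(d.positions))],
        "chrom": d.interval.chrom,
        "start": list(d.positions),
        "end": [p + width for p in d.positions],
        "value": list(d.values),
        "kind": d.kind,
    })
    write_tsv(path, df, cfg, seed)


def read_dosage(path) -> RegionDosage:
    df = read_tsv(path, DOSAGE_COLUMNS)
    kinds = df["kind"].unique()
    if len(kinds) != 1:
        raise ValueError(f"{path}: mixed dosage kinds {list(kinds)}")
    df = df.sort_values("start")
    return RegionDosage(
        GenomeInterval(str(df["chrom"].iloc[0]), int(df["start"].min()),
                       int(df["end"].max())),
        tuple(int(x) for x in df["start"]),
        tuple(float(x) for x in df["value"]),
        str(kinds[0]),
    )


def write_fasta(path, records: dict) -> None:
    """records: name -> sequence string."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def haplotype_to_bed(hap: Haplotype, name: str | None = None) -> str:
    """BED6 of a haplotype's annotated elements (haplotype-frame coords,
    strand column from the element orientation)."""
    chrom = name or hap.label
    lines = []
    for el in hap.elements:
        strand = "+" if el.orientation > 0 else "-"
        lines.append(f"{chrom}\t{el.start}\t{el.end}\t{el.name}\t0\t{strand}")
    return "\n".join(lines) + "\n"


def architecture_to_bed(arch: LocusArchitecture) -> str:
    lines = []
    for c in arch.lcr_copies:
        strand = "+" if c.orientation > 0 else "-"
        lines.append(f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                     f"\t{c.name}\t0\t{strand}")
    g = arch.gene
    lines.append(f"{g.chrom}\t{g.start}\t{g.end}\tNPHP1\t0\t{g.strand}")
    return "\n".join(sorted(lines, key=lambda l: int(l.split("\t")[1]))) + "\n"
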