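"""Run configuration: input paths plus every analysis threshold.

Defaults are the thresholds used throughout the package: 3x CpG coverage,
-100/+700 promoter window, +/-2 kb proximal window, 50% high-methylation
cut, log2 expression cuts 1.5/2.5, P < 0.05 with fold change > 1.2, 20-kb
neighbourhood, +/-2,500 bp profile flank with 100-bp bins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    annotation: str = ""
    chrom_sizes: str = ""
    methylation_a: str = ""
    methylation_b: str = ""
    expression: str = ""
    cgi: str | None = None
    tsg: str | None = None
    promoter_fasta: str | None = None
    # mark -> condition -> [rep1.bed, rep2.bed]
    peaks: dict = field(default_factory=dict)

    condition_a: str = "parental"
    condition_b: str = "demethylated"
    methylation_dialect: str = "percent"

    min_coverage: int = 3
    promoter_upstream: int = 100
    promoter_downstream: int = 700
    proximal_window: int = 2000
    high_meth_threshold: float = 0.5
    low_expression_cut: float = 1.5
    high_expression_cut: float = 2.5
    p_cut: float = 0.05
    fc_cut: float = 1.2
    near: int = 20_000
    profile_flank: int = 2500
    profile_bin: int = 100
    n_random_regions: int = 1000
    random_region_length: int = 10_000
    tata_motif: str = "TATAWAW"
    tata_max_mismatch: int = 1

    seed: int = 1
    outdir: str = "results/analysis"

    def validate(self) -> None:
        if self.min_coverage < 1:
            raise ConfigError("min_coverage must be >= 1")
        if not (0.0 < self.high_meth_threshold < 1.0):
            raise ConfigError("high_meth_threshold must lie in (0, 1)")
        if not self.low_expression_cut < self.high_expression_cut:
            raise ConfigError("low_expression_cut must be below high_expression_cut")
        if not (0.0 < self.p_cut <= 1.0):
            raise ConfigError("p_cut must lie in (0, 1]")
        if self.fc_cut < 1.0:
            raise ConfigError("fc_cut must be >= 1")
        if self.proximal_window <= 0 or self.near < 0:
            raise ConfigError("windows must be positive")
        if self.profile_flank % self.profile_bin != 0:
            raise ConfigError("profile_flank must be divisible by profile_bin")
        if min(self.promoter_upstream, self.promoter_downstream) < 0:
            raise ConfigError("promoter window offsets must be >= 0")
        if self.n_random_regions <= 0:
            raise ConfigError("n_random_regions must be > 0")
        if self.methylation_dialect not in ("percent", "fraction"):
            raise ConfigError(f"unknown dialect {self.methylation_dialect!r}")

    def required_paths(self) -> dict[str, str]:
        out = {
            "annotation": self.annotation,
            "chrom_sizes": self.chrom_sizes,
            "methylation_a": self.methylation_a,
            "methylation_b": self.methylation_b,
            "expression": self.expression,
        }
        for mark, conds in self.peaks.items():
            for cond, files in conds.items():
                for i, f in enumerate(files):
                    out[f"peaks.{mark}.{cond}.rep{i + 1}"] = f
        return out

    def check_paths(self) -> None:
        for key, path in self.required_paths().items():
            if not path:
                raise ConfigError(f"missing input path for {key}")
            if not Path(path).exists():
                raise ConfigError(f"input {key} not found: {path}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def for_bundle(cls, bundle_dir, outdir="results/analysis", seed: int = 1,
                   condition_a: str = "parental", condition_b: str = "demethylated",
                   **overrides) -> "RunConfig":
        """Point every input at the standard synthetic-bundle layout."""
        d = Path(bundle_dir)
        peaks = {}
        for mark in ("H3K4me3", "H3K27ac", "RNAPII", "H3K4me1"):
            conds = {}
            for cond in (condition_a, condition_b):
                files = [
                    str(d / "peaks" / f"{mark.lower()}_{cond}_rep{r}.bed")
                    for r in (1, 2)
                ]
                if all(Path(f).exists() for f in files):
                    conds[cond] = files
            if conds:
                peaks[mark] = conds
        cfg = cls(
            annotation=str(d / "annotation.gtf"),
            chrom_sizes=str(d / "chrom_sizes.tsv"),
            methylation_a=str(d / f"methylation_{condition_a}.tsv"),
            methylation_b=str(d / f"methylation_{condition_b}.tsv"),
            expression=str(d / "expression.tsv"),
            cgi=str(d / "cgi.bed") if (d / "cgi.bed").exists() else None,
            tsg=str(d / "tsg.tsv") if (d / "tsg.tsv").exists() else None,
            promoter_fasta=(
                str(d / "promoters.fasta") if (d / "promoters.fasta").exists() else None
            ),
            peaks=peaks,
            condition_a=condition_a,
            condition_b=condition_b,
            outdir=str(outdir),
            seed=seed,
            **overrides,
        )
        cfg.validate()
        return cfg
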