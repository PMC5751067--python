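"""Pipeline configuration: the handful of printed constants the curation
procedure depends on, serializable to a flat ``key: value`` text file."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .errors import ParseError, ValidationError

#: minimum repeat-unit counts for SSR detection, by unit length:
#: 10 repeats for mono-, 6 for di-, 5 for tri- through hepta-nucleotide.
DEFAULT_SSR_MIN_UNITS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5, 7: 5}


@dataclass
class PipelineConfig:
    kmer_size: int = 17
    error_multiplicity_max: int = 1
    coverage_removal_threshold: float = 0.80  # discard short contig at >=80% aligned
    min_restore_identity: float = 0.90  # below this a removal is auto-restored
    mito_coverage_threshold: float = 0.80
    mito_evalue_max: float = 1e-5
    blob_coverage_min: float = 10.0
    max_chain_gap: int = 500  # bp, block-merge gap on both sequences
    anchor_k: int = 21
    ssr_min_units: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_SSR_MIN_UNITS)
    )
    compound_max_interruption: int = 100  # bp between SSRs fused into a compound
    marker_flank_exclusion: int = 2000  # bp window that must be free of other SSRs
    marker_flank_len: int = 200  # bp flank that must be unique in the assembly
    rng_seed: int = 0

    def __post_init__(self):
        for name in (
            "coverage_removal_threshold",
            "min_restore_identity",
            "mito_coverage_threshold",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0,1]")
        if self.mito_evalue_max < 0:
            raise ValidationError("mito_evalue_max must be >= 0")
        if self.kmer_size < 1 or self.anchor_k < 11:
            raise ValidationError("kmer_size >= 1 and anchor_k >= 11 required")
        for k, v in self.ssr_min_units.items():
            if not (1 <= k <= 7) or v < 1:
                raise ValidationError(f"bad ssr_min_units entry {k}:{v}")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if f.name == "ssr_min_units":
                    v = ",".join(f"{k}:{n}" for k, n in sorted(v.items()))
                fh.write(f"{f.name}: {v}\n")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if ":" not in line:
                    raise ParseError("expected 'key: value'", path, lineno)
                key, _, val = line.partition(":")
                raw[key.strip()] = val.strip()
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for key, val in raw.items():
            if key not in types:
                raise ParseError(f"unknown config key {key!r}", path)
            if key == "ssr_min_units":
                kwargs[key] = {
                    int(k): int(n)
                    for k, n in (item.split(":") for item in val.split(","))
                }
            elif key in ("kmer_size", "error_multiplicity_max", "max_chain_gap",
                         "anchor_k", "compound_max_interruption",
                         "marker_flank_exclusion", "marker_flank_len", "rng_seed"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)
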