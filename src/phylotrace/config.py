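"""Run-wide configuration.

All thresholds of the MRD caller and the clonal-deconvolution steps live here so
that a single object can be serialised into every output header.  Defaults are
the values used throughout the package's reference analyses.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields


@dataclass(frozen=True)
class RunConfig:
    """Global thresholds and the master seed.

    Parameters
    ----------
    alpha_mrd : float
        Significance threshold of the one-tailed exact Poisson sample-level
        ctDNA test.
    alpha_presence : float
        Significance threshold for clone- and tumour-presence calls.
    er_upper_limit : float
        A tracked variant whose trinucleotide-context error-rate upper 95%
        confidence bound exceeds this value is excluded from calling
        (0.01% by default).
    vaf_exclusion : float
        Background positions with a per-alternate VAF above this value are
        excluded from error-rate estimation (possible germline variants or
        clonal haematopoiesis).
    sd_threshold : float
        Normalised-SD (coefficient of variation) ceiling above which a
        clone's CCF distribution is flagged poor quality.
    sweep_p : float
        Rank-sum p-value above which a subclone is compatible with 100% CCF.
    sweep_ccf : float
        Mean-CCF floor for calling a clonal sweep.
    high_sens_level, high_sens_ng : float
        Clonal ctDNA level and assay input defining a "high subclone
        sensitivity" sample.
    representative_n_mut : int
        Number of mutations of the hypothetical representative subclone used
        for per-sample minimal detectable CCF.
    strand_bias_p : float
        p-value threshold of the binomial strand-bias filters.
    strand_bias_min_alt : int
        Minimum alternate reads before a strand-bias flag may be raised.
    seed : int
        Master seed; per-stage seeds are derived deterministically from it.
    """

    alpha_mrd: float = 0.01
    alpha_presence: float = 0.01
    er_upper_limit: float = 1e-4
    vaf_exclusion: float = 0.01
    sd_threshold: float = 0.56
    sweep_p: float = 0.05
    sweep_ccf: float = 0.90
    high_sens_level: float = 0.001
    high_sens_ng: float = 10.0
    representative_n_mut: int = 4
    strand_bias_p: float = 0.01
    strand_bias_min_alt: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "seed":
                continue
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"config field {f.name!r} must be positive, got {v!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Short stable hash of the configuration, for output provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed below 2**31."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


_TYPES = {f.name: f.type for f in fields(RunConfig)}


def validate_config(path) -> RunConfig:
    """Parse a ``key=value`` config file into a :class:`RunConfig`.

    Unknown keys are rejected; missing keys take the defaults above.
    """
    values: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected key=value, got {line!r}")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in _TYPES:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            caster = int if key in ("representative_n_mut", "seed", "strand_bias_min_alt") else float
            try:
                values[key] = caster(raw)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: key {key!r}: {exc}") from None
    return RunConfig(**values)
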