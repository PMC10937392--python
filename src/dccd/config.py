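"""Run configuration: a flat ``key = value`` text dialect plus defaults.

Every pipeline run writes its fully resolved configuration (including the
seed) next to the outputs so the run can be reproduced bit-exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path


@dataclass
class RunConfig:
    """All tunables of the end-to-end pipeline.

    Threshold defaults mirror the printed procedure: top 60 markers per
    cluster at |log2FC| > 1 and adjusted p < 0.001; subtype signatures at
    |log2FC| > 1 and adjusted p < 0.01; OR calls at adjusted p < 0.05;
    NTP with 1,000 permutations; k pinned at 4.
    """

    seed: int = 0
    output_dir: str = "dccd_run"
    # marker extraction
    marker_log2fc_cutoff: float = 1.0
    marker_padj_cutoff: float = 1e-3
    marker_top_n: int = 60
    # subtype signatures / differential abundance
    subtype_log2fc_cutoff: float = 1.0
    subtype_padj_cutoff: float = 0.01
    diff_log2fc_cutoff: float = 1.0
    diff_padj_cutoff: float = 0.01
    or_padj_cutoff: float = 0.05
    # ssGSEA
    ssgsea_alpha: float = 0.25
    # consensus clustering
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_resamples: int = 1000
    subsample_fraction: float = 0.8
    pinned_k: int = 4
    # NTP
    ntp_nperm: int = 1000
    ntp_seed: int = 42

    def __post_init__(self) -> None:
        if any(k < 2 for k in self.k_range):
            raise ValueError("k_range values must be >= 2")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{f.name} must be finite")

    def to_file(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            for key, val in asdict(self).items():
                if isinstance(val, tuple):
                    val = ",".join(str(v) for v in val)
                fh.write(f"{key} = {val}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"malformed config line: {line!r}")
                key, val = (s.strip() for s in line.split("=", 1))
                raw[key] = val
        kwargs: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        for key, val in raw.items():
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(defaults, key)
            if isinstance(default, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            elif isinstance(default, tuple):
                kwargs[key] = tuple(int(v) for v in val.split(",") if v)
            else:
                kwargs[key] = val
        return cls(**kwargs)
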