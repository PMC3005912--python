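"""Run configuration: flat key = value files overridden by CLI flags."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, fields


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    d is the minimum common-region length entering the similarity
    numerator; disorder_min_len / disorder_merge_gap are the
    disorder-region cleaning thresholds (regions < 10 residues ignored,
    separations < 3 residues merged); disorder_threshold binarises
    per-residue scores.
    """

    d: int = 2
    d_filter_mode: str = "numerator"  # or "both"
    expand_on_tie: bool = False
    disorder_min_len: int = 10
    disorder_merge_gap: int = 3
    disorder_threshold: float = 0.5
    disorder_order: str = "merge_then_filter"
    gap_open: float = -10.0
    gap_extend: float = -1.0
    skip_if_all_equal: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        values: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str,
                 "bool": lambda v: v.lower() in ("1", "true", "yes", "on")}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = casts[types[key]](value)
        return cls(**values)

    def as_dict(self) -> dict:
        return asdict(self)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
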