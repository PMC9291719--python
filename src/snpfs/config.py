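"""Analysis configuration, seed derivation, and the append-only run ledger."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml


def derive_seed(base_seed: int, *key: int) -> int:
    """Deterministic child seed from a base seed and a counter tuple.

    Uses numpy's SeedSequence over (base_seed, *key); no global RNG state.
    The result fits in a signed 32-bit integer.
    """
    return int(np.random.SeedSequence([int(base_seed), *map(int, key)]).generate_state(1)[0] % 2**31)


@dataclass
class AnalysisConfig:
    """Everything a full workflow run needs, serializable and hashable."""

    # synthetic-cohort scale
    n_samples: int = 2000
    n_druggable: int = 1
    connected_per_druggable: int = 10
    snps_per_gene: int = 10
    ld_block_size: int = 10
    ld_rho: float = 0.3
    n_subpops: int = 1
    pass_fraction: float = 0.8
    # planted signal
    causal_fs_index: int = 0
    n_causal_snps: int = 4
    causal_beta: float = 0.9
    # stage parameters
    n_runs: int = 20
    population: int = 10
    generations: int = 20
    fractions: tuple = (0.75, 0.13, 0.12)
    resadj: bool = False
    n_permutations: int = 5
    # explanation
    k_background: int | None = None
    k_clusters: int | None = None
    k_range: tuple = (2, 8)
    n_coalitions: str | int = "auto"  # "all" below 13 features, sampled above
    # seeding
    base_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(self.fractions)
        d["k_range"] = list(self.k_range)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)


@dataclass
class RunLedger:
    """Append-only JSON-lines record of every search run executed."""

    path: Path
    records: list = field(default_factory=list)

    def append(self, **record) -> None:
        self.records.append(record)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(record, default=str) + "\n")

    def count(self, **filters) -> int:
        return sum(
            1
            for r in self.records
            if all(r.get(k) == v for k, v in filters.items())
        )

    @classmethod
    def read(cls, path) -> "RunLedger":
        records = []
        p = Path(path)
        if p.exists():
            with open(p) as fh:
                records = [json.loads(line) for line in fh if line.strip()]
        return cls(p, records)
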