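"""Background and foreground sequence simulators.

The null (background) model draws two independent i.i.d. uniform sequences
over {A, C, G, T}.  The alternative (foreground) model implants a shared
module — one random L-mer per replicate — into both sequences at identical
coordinates: the candidate sites are the non-overlapping grid positions
0, L, 2L, ..., and each site is selected independently with a Bernoulli
implant probability.  The implanted pair is detectably similar while each
member remains marginally uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmers import ALPHABET, InvalidParameterError, NucleotideSequence

__all__ = [
    "ForegroundConfig",
    "SimulatedPair",
    "random_background",
    "implant_modules",
    "generate_pair",
]

DEFAULT_IMPLANT_PROB = 0.05  # per grid site; detectable but unsaturated

_LETTERS = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class ForegroundConfig:
    """Shared-module implantation parameters.

    L            -- module length (the implanted L-mer), >= 1
    implant_prob -- Bernoulli selection probability per candidate grid site
    """

    L: int
    implant_prob: float = DEFAULT_IMPLANT_PROB

    def __post_init__(self) -> None:
        if self.L < 1:
            raise InvalidParameterError(f"L must be >= 1, got {self.L}")
        if not 0 <= self.implant_prob <= 1:
            raise InvalidParameterError(
                f"implant_prob must be in [0, 1], got {self.implant_prob}"
            )


@dataclass(frozen=True)
class SimulatedPair:
    """A simulated sequence pair with its implant record."""

    x: NucleotideSequence
    y: NucleotideSequence
    implant_sites: tuple[tuple[int, int], ...]  # half-open, shared coords
    module: str  # empty for null pairs
    seed: int

    def to_dict(self) -> dict:
        return {
            "x_id": self.x.id,
            "y_id": self.y.id,
            "length": len(self.x),
            "module": self.module,
            "module_length": len(self.module),
            "implant_sites": [list(s) for s in self.implant_sites],
            "seed": self.seed,
        }


def _random_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _LETTERS[codes].tobytes().decode("ascii")


def random_background(
    length: int, seed: int | np.random.Generator, id: str = "bg"
) -> NucleotideSequence:
    """One i.i.d. uniform sequence of the given length (reproducible)."""
    if length < 1:
        raise InvalidParameterError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    return NucleotideSequence(id, _codes_to_str(_random_codes(rng, length)))


def implant_modules(
    x: NucleotideSequence,
    y: NucleotideSequence,
    cfg: ForegroundConfig,
    seed: int | np.random.Generator,
) -> SimulatedPair:
    """Implant one shared random L-mer into both sequences.

    Candidate sites are [iL, (i+1)L) for i = 0 .. floor(n/L)−1; each is
    selected independently with ``cfg.implant_prob``.  Both sequences are
    overwritten with the same module at every selected site, so implants
    are non-overlapping by construction.
    """
    if len(x) != len(y):
        raise InvalidParameterError(
            f"sequences must have equal length ({len(x)} vs {len(y)})"
        )
    n = len(x)
    if cfg.L > n:
        raise InvalidParameterError(f"L={cfg.L} exceeds sequence length {n}")
    rng = np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, int) else -1
    module_codes = _random_codes(rng, cfg.L)
    n_sites = n // cfg.L
    selected = rng.random(n_sites) < cfg.implant_prob
    xc = np.frombuffer(x.residues.encode("ascii"), dtype=np.uint8).copy()
    yc = np.frombuffer(y.residues.encode("ascii"), dtype=np.uint8).copy()
    module_bytes = _LETTERS[module_codes]
    sites = []
    for i in np.flatnonzero(selected):
        start = int(i) * cfg.L
        end = start + cfg.L
        xc[start:end] = module_bytes
        yc[start:end] = module_bytes
        sites.append((start, end))
    return SimulatedPair(
        x=NucleotideSequence(x.id, xc.tobytes().decode("ascii")),
        y=NucleotideSequence(y.id, yc.tobytes().decode("ascii")),
        implant_sites=tuple(sites),
        module=_codes_to_str(module_codes),
        seed=seed_val,
    )


def generate_pair(
    length: int,
    cfg: ForegroundConfig,
    null: bool,
    seed: int | np.random.Generator,
    ids: tuple[str, str] = ("X", "Y"),
) -> SimulatedPair:
    """One replicate pair: background-only if ``null``, else implanted.

    All randomness flows through a single generator derived from ``seed``,
    so the pair is bit-reproducible.
    """
    if length < cfg.L:
        raise InvalidParameterError(
            f"length {length} is shorter than module length L={cfg.L}"
        )
    rng = np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, int) else -1
    x = NucleotideSequence(ids[0], _codes_to_str(_random_codes(rng, length)))
    y = NucleotideSequence(ids[1], _codes_to_str(_random_codes(rng, length)))
    if null:
        return SimulatedPair(
            x=x, y=y, implant_sites=(), module="", seed=seed_val
        )
    pair = implant_modules(x, y, cfg, rng)
    return SimulatedPair(
        x=pair.x,
        y=pair.y,
        implant_sites=pair.implant_sites,
        module=pair.module,
        seed=seed_val,
    )
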