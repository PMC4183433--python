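"""Mechanistic model of minimal-pairing 3' primer extension.

A single-stranded oligo can prime synthesis either intramolecularly
(snapback: the 3' terminus folds back onto an upstream region of the same
strand) or intermolecularly (against another oligo).  A priming register
requires a run of contiguous antiparallel Watson-Crick pairs ending at the
3' terminus; extension then copies the template 5'-ward, appending the
complement of each template base.  Slippage dissociates the extended end
and reprimes it at another register, so products can accrete repeated
blocks over several cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError
from .sequences import WC_PAIR, validate_dna


@dataclass(frozen=True)
class Oligo:
    """A 5'->3' single-stranded DNA oligo."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_dna(self.sequence, what=f"oligo {self.id}"))
        if not self.sequence:
            raise InvalidArgumentError(f"oligo {self.id} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimingConfig:
    """A register at which a primer 3' terminus pairs with a template.

    ``register`` is the 1-based template position paired with the primer's
    3'-terminal base; pairing is antiparallel, so primer base L-i pairs
    with template position register+i.  ``paired_len`` is the length of
    the maximal contiguous WC run ending at the terminus.
    """

    mode: str  # "snapback" | "intermolecular"
    template_id: str
    register: int
    paired_len: int

    def __post_init__(self) -> None:
        if self.mode not in ("snapback", "intermolecular"):
            raise InvalidArgumentError(f"unknown priming mode {self.mode!r}")
        if self.register < 1 or self.paired_len < 1:
            raise InvalidArgumentError("register and paired_len must be >= 1")


@dataclass(frozen=True)
class ExtensionProduct:
    sequence: str
    trace: tuple[str, ...]
    probability_weight: float = 1.0

    @property
    def length(self) -> int:
        return len(self.sequence)


def _paired_run_len(primer: str, template: str, register: int) -> int:
    """Length of the contiguous WC run pairing the primer 3' terminus at
    ``register`` (1-based template position), walking 5'-ward on the
    primer and 3'-ward on the template."""
    k = 0
    L = len(primer)
    T = len(template)
    while k < L and register - 1 + k < T:
        if WC_PAIR[primer[L - 1 - k]] != template[register - 1 + k]:
            break
        k += 1
    return k


def enumerate_priming_configs(
    oligo: Oligo,
    templates: list[Oligo] | None = None,
    min_pair: int = 1,
    include_snapback: bool = True,
) -> list[PrimingConfig]:
    """All registers where >= ``min_pair`` contiguous WC pairs end at the
    oligo's 3' terminus.

    Snapback configurations pair the terminus with an upstream region of
    the same molecule; the paired template region must not overlap the
    primer's own 3'-terminal pairing bases.  Intermolecular
    configurations are enumerated against every template (including the
    oligo's own sequence if passed, modelling pairing between two copies).
    The result is exhaustive and duplicate-free; an empty list means the
    oligo cannot prime.
    """
    if min_pair < 1:
        raise InvalidArgumentError("min_pair must be >= 1")
    templates = templates or []
    configs: list[PrimingConfig] = []
    seen: set[tuple[str, str, int]] = set()

    if include_snapback:
        L = len(oligo)
        for register in range(1, L + 1):
            k = _paired_run_len(oligo.sequence, oligo.sequence, register)
            if k < min_pair:
                continue
            # paired template region [register, register+k-1] must stay
            # clear of the primer's own 3'-terminal k bases [L-k+1, L]
            if register + k - 1 > L - k:
                continue
            key = ("snapback", oligo.id, register)
            if key not in seen:
                seen.add(key)
                configs.append(PrimingConfig("snapback", oligo.id, register, k))

    for tmpl in templates:
        for register in range(1, len(tmpl) + 1):
            k = _paired_run_len(oligo.sequence, tmpl.sequence, register)
            if k < min_pair:
                continue
            key = ("intermolecular", tmpl.id, register)
            if key not in seen:
                seen.add(key)
                configs.append(PrimingConfig("intermolecular", tmpl.id, register, k))
    return configs


def can_self_prime(oligo: Oligo, min_pair: int = 1) -> bool:
    """True iff the oligo has any priming register against itself
    (snapback or between two copies)."""
    return bool(enumerate_priming_configs(oligo, [oligo], min_pair))


def extend_once(config: PrimingConfig, oligo: Oligo, template: Oligo) -> ExtensionProduct:
    """Extend ``oligo`` once at ``config``: append the complement of the
    template bases 5' of the paired region, walking to the template 5'
    end.  A register already at the 5' end yields a zero-extension
    product (valid; length unchanged)."""
    if config.template_id != template.id:
        raise InvalidArgumentError(
            f"config is for template {config.template_id!r}, got {template.id!r}"
        )
    k = _paired_run_len(oligo.sequence, template.sequence, config.register)
    if k < config.paired_len:
        raise InvalidArgumentError("config pairing is not supported by the given sequences")
    appended = "".join(
        WC_PAIR[template.sequence[pos - 1]] for pos in range(config.register - 1, 0, -1)
    )
    trace = (
        f"prime({config.mode},{config.template_id},{config.register},{config.paired_len})",
        f"extend({len(appended)})",
    )
    return ExtensionProduct(sequence=oligo.sequence + appended, trace=trace)


def simulate_products(
    oligo: Oligo,
    n_molecules: int = 100,
    cycles: int = 10,
    slippage_prob: float = 0.0,
    min_pair: int = 1,
    seed: int = 0,
    templates: list[Oligo] | None = None,
) -> list[ExtensionProduct]:
    """Seeded stochastic extension of ``n_molecules`` copies of ``oligo``.

    Each molecule repeatedly primes (choice among available configs
    weighted by 2^paired_len, so longer pairing is favoured), extends to
    the template 5' end, then with probability ``slippage_prob``
    dissociates and reprimes, up to ``cycles`` cycles.  Intermolecular
    priming uses unextended copies of the input oligo plus any extra
    ``templates``.  Returns distinct products with weights summing to
    n_molecules; deterministic for a fixed seed.
    """
    if n_molecules < 1:
        raise InvalidArgumentError("n_molecules must be >= 1")
    if not 0 <= slippage_prob <= 1:
        raise InvalidArgumentError("slippage_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    template_pool = [oligo] + list(templates or [])
    by_id = {t.id: t for t in template_pool}

    tally: dict[tuple[str, tuple[str, ...]], float] = {}
    for _ in range(n_molecules):
        current = oligo
        trace: list[str] = []
        for cycle in range(cycles):
            configs = enumerate_priming_configs(current, template_pool, min_pair)
            if not configs:
                break
            weights = np.array([2.0 ** c.paired_len for c in configs])
            weights /= weights.sum()
            cfg = configs[int(rng.choice(len(configs), p=weights))]
            if cfg.mode == "snapback":
                template = current
            else:
                template = by_id[cfg.template_id]
            product = extend_once(cfg, current, template)
            trace.extend(product.trace)
            current = Oligo(id=current.id, sequence=product.sequence)
            if cycle + 1 < cycles and rng.random() < slippage_prob:
                trace.append("slip")
                continue
            break
        key = (current.sequence, tuple(trace))
        tally[key] = tally.get(key, 0.0) + 1.0

    products = [
        ExtensionProduct(sequence=seq, trace=tr, probability_weight=w / n_molecules)
        for (seq, tr), w in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return products


def decode_trace(oligo: Oligo, trace: tuple[str, ...], templates: list[Oligo]) -> str:
    """Replay a product trace against its templates, reproducing the
    product sequence (template-fidelity check)."""
    by_id = {t.id: t for t in ([oligo] + templates)}
    current = oligo.sequence
    i = 0
    events = list(trace)
    while i < len(events):
        ev = events[i]
        if ev.startswith("prime("):
            mode, tid, register, k = ev[6:-1].split(",")
            register = int(register)
            tmpl = current if mode == "snapback" else by_id[tid].sequence
            appended = "".join(WC_PAIR[tmpl[pos - 1]] for pos in range(register - 1, 0, -1))
            nxt = events[i + 1]
            assert nxt == f"extend({len(appended)})", "trace extend length mismatch"
            current = current + appended
            i += 2
        elif ev == "slip":
            i += 1
        else:  # pragma: no cover - defensive
            raise InvalidArgumentError(f"unknown trace event {ev!r}")
    return current
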