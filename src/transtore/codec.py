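"""Byte <-> trit <-> transition-template conversion.

Information is carried by transitions between non-identical nucleotides:
each position of a template sequence differs from its predecessor, so every
extension step has 3 choices and carries one trit (log2 3 ~ 1.585 bits).
A template of K nucleotides interleaves information-bearing positions with
predetermined synchronization nucleotides ("scaffold") used by the decoder
to re-anchor strands that lost nucleotides during synthesis.

The encode path per template is::

    address || data  (Omega bits)
      -> ECC encode  (B bits)
      -> base-3 packing  (n_info trits)
      -> transition modulation + sync insertion  (K nucleotides)

and decoding inverts each stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import yaml

from .bch import BCHCode

NUCLEOTIDES = "ACGT"
LOG2_3 = math.log2(3.0)

__all__ = [
    "NUCLEOTIDES",
    "LOG2_3",
    "TransitionTable",
    "TemplateSequence",
    "CodecProfile",
    "Scaffold",
    "AddressedPayload",
    "CapacityError",
    "ReassemblyError",
    "bits_to_trits",
    "trits_to_bits",
    "modulate",
    "demodulate",
    "build_scaffold",
    "ecc_encode",
    "ecc_decode",
    "encode_message",
    "decode_templates",
    "capacity",
    "cyclic_successor",
    "builtin_profile",
    "BUILTIN_PROFILES",
]


class CapacityError(ValueError):
    """Payload does not fit the profile's address space."""


class ReassemblyError(ValueError):
    """Template set has duplicate or missing addresses."""

    def __init__(self, message: str, missing=(), duplicated=()):
        super().__init__(message)
        self.missing = tuple(missing)
        self.duplicated = tuple(duplicated)


def _check_base(base: str) -> str:
    if base not in NUCLEOTIDES:
        raise ValueError(f"invalid nucleotide {base!r}")
    return base


def cyclic_successor(base: str) -> str:
    """Next base in the fixed cycle A -> C -> G -> T -> A (never equal to its input)."""
    return NUCLEOTIDES[(NUCLEOTIDES.index(_check_base(base)) + 1) % 4]


class TransitionTable:
    """Bijective map (previous base, trit) -> next base, next base != previous.

    The canonical table maps, for each previous base, the three other bases in
    alphabetical order to trits 0, 1, 2. Any bijection works; tables are
    serializable so an alternative mapping can be swapped in via config.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        if mapping is None:
            mapping = {p: "".join(b for b in NUCLEOTIDES if b != p) for p in NUCLEOTIDES}
        for prev, nxt in mapping.items():
            _check_base(prev)
            if sorted(nxt) != sorted(b for b in NUCLEOTIDES if b != prev):
                raise ValueError(
                    f"row for {prev!r} must be a permutation of the three bases != {prev!r}"
                )
        if set(mapping) != set(NUCLEOTIDES):
            raise ValueError("table must have a row for each of A, C, G, T")
        self._next = dict(mapping)
        self._trit = {
            (p, b): t for p, row in mapping.items() for t, b in enumerate(row)
        }

    def next_base(self, previous: str, trit: int) -> str:
        if trit not in (0, 1, 2):
            raise ValueError(f"invalid trit {trit!r}")
        return self._next[_check_base(previous)][trit]

    def trit(self, previous: str, nxt: str) -> int:
        try:
            return self._trit[(previous, nxt)]
        except KeyError:
            raise ValueError(f"invalid transition {previous!r} -> {nxt!r}") from None

    def to_dict(self) -> dict[str, str]:
        return dict(self._next)

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "TransitionTable":
        return cls(dict(d))

    def __eq__(self, other) -> bool:
        return isinstance(other, TransitionTable) and self._next == other._next


@dataclass(frozen=True)
class TemplateSequence:
    """A designed transition sequence: no two adjacent bases identical.

    ``ligation_tail`` is the terminal nucleotide appended for adapter ligation
    (a polyC tail in the wet protocol); it is part of what gets synthesized
    but not of the K information/sync positions.
    """

    bases: str
    initiator_terminal: str = "G"
    ligation_tail: str = ""
    label: str = ""

    def __post_init__(self):
        _check_base(self.initiator_terminal)
        for b in self.bases:
            _check_base(b)
        if self.bases and self.bases[0] == self.initiator_terminal:
            raise ValueError("first base equals initiator terminal (self-transition)")
        for a, b in zip(self.bases, self.bases[1:]):
            if a == b:
                raise ValueError(f"self-transition {a}{b} in template")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def synthesis_bases(self) -> str:
        """Bases dispensed cycle by cycle, including any ligation tail."""
        return self.bases + self.ligation_tail

    @property
    def expected_compressed_length(self) -> int:
        """Length of a perfectly synthesized strand after run-length compression."""
        n = len(self.bases)
        if self.ligation_tail and (not self.bases or self.bases[-1] != self.ligation_tail):
            n += len(self.ligation_tail)
        return n


@dataclass(frozen=True)
class Scaffold:
    """Positions (0-based) and identities of synchronization nucleotides.

    Identity is either given by ``identity_rule(position, previous_base)``
    (the default rule is the cyclic successor of the previous base, which can
    never collide with it) or fixed explicitly via :meth:`from_identities`.
    """

    positions: tuple[int, ...]
    identity_rule: Callable[[int, str], str] = field(
        default=lambda pos, prev: cyclic_successor(prev), compare=False
    )
    fixed_identities: tuple[str, ...] | None = None

    def __post_init__(self):
        if any(b < a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("scaffold positions must be strictly increasing")
        if self.fixed_identities is not None and len(self.fixed_identities) != len(
            self.positions
        ):
            raise ValueError("one identity per position required")

    @classmethod
    def from_identities(cls, positions: Sequence[int], bases: Sequence[str]) -> "Scaffold":
        positions = tuple(positions)
        bases = tuple(bases)
        lookup = dict(zip(positions, bases))
        return cls(
            positions=positions,
            identity_rule=lambda pos, prev: lookup[pos],
            fixed_identities=bases,
        )

    def identity(self, position: int, previous: str) -> str:
        base = self.identity_rule(position, previous)
        if base == previous:
            raise ValueError("scaffold identity equals previous base")
        return base

    def consistent(self, bases: str, initiator_terminal: str | None = None) -> bool:
        """True if every sync position of ``bases`` carries its scaffold identity."""
        for p in self.positions:
            prev = bases[p - 1] if p > 0 else initiator_terminal
            if prev is None:
                continue
            if bases[p] != self.identity(p, prev):
                return False
        return True


def _n_info_for(K: int, sync_period: int) -> int:
    """Number of information positions: n + floor(n / period) == K."""
    if sync_period <= 0:
        return K
    for n in range(K + 1):
        if n + n // sync_period == K:
            return n
    raise ValueError(f"no info/sync split of K={K} with sync_period={sync_period}")


@dataclass(frozen=True)
class CodecProfile:
    """The (K, B, Omega) triple plus addressing, sync layout and ECC.

    K
        template length in nucleotides (information + synchronization).
    B
        ECC-encoded bits per template.
    omega
        information bits (address + data) per template; omega <= B.
    sync_period
        information nucleotides between synchronization nucleotides
        (0 disables the scaffold).
    field_packing
        "joint": the whole B-bit block is one big-endian integer converted to
        base 3; "separate": address and data fields are converted separately
        (the per-character scheme used for the un-coded hello-world layout).
    """

    name: str
    K: int
    B: int
    omega: int
    address_bits: int
    sync_period: int = 0
    ecc_spec: str = "none"
    initiator_terminal: str = "G"
    field_packing: str = "joint"
    terminal_c_tail: bool = False

    def __post_init__(self):
        _check_base(self.initiator_terminal)
        if self.omega > self.B:
            raise ValueError("omega must not exceed B")
        if self.address_bits > self.omega:
            raise ValueError("address_bits must not exceed omega")
        if self.field_packing not in ("joint", "separate"):
            raise ValueError("field_packing must be 'joint' or 'separate'")
        n_info = self.n_info
        if 3**n_info < 2**self.B:
            raise ValueError(
                f"trit capacity too small: 3^{n_info} < 2^{self.B}"
            )
        if self.omega / self.K > LOG2_3:
            raise ValueError("profile exceeds the log2(3) bits/nt ceiling")
        if self.field_packing == "separate":
            aw, dw = self._separate_widths()
            if dw < 1 or 3**aw < 2**self.address_bits:
                raise ValueError("separate field packing does not fit info positions")

    @property
    def n_info(self) -> int:
        return _n_info_for(self.K, self.sync_period)

    @property
    def n_sync(self) -> int:
        return self.K - self.n_info

    @property
    def data_bits(self) -> int:
        return self.omega - self.address_bits

    @property
    def bits_per_nucleotide(self) -> float:
        return self.omega / self.K

    def _separate_widths(self) -> tuple[int, int]:
        # address gets the minimal trit width; data takes the remaining info
        # positions (so a data value may exceed the trit field only if the
        # payload uses the top of the byte range, e.g. bytes >= 243 for the
        # 5-trit hello-world field — a range error at encode time).
        aw = _min_trit_width(self.address_bits)
        return aw, self.n_info - aw

    def ecc(self) -> BCHCode | None:
        return BCHCode.from_spec(self.ecc_spec, self.omega, self.B)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "K": self.K,
            "B": self.B,
            "omega": self.omega,
            "address_bits": self.address_bits,
            "sync_period": self.sync_period,
            "ecc_spec": self.ecc_spec,
            "initiator_terminal": self.initiator_terminal,
            "field_packing": self.field_packing,
            "terminal_c_tail": self.terminal_c_tail,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodecProfile":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CodecProfile":
        return cls.from_dict(yaml.safe_load(text))


def _min_trit_width(nbits: int) -> int:
    """Smallest w with 3**w >= 2**nbits."""
    w = 0
    while 3**w < 2**nbits:
        w += 1
    return w


@dataclass(frozen=True)
class AddressedPayload:
    address: int
    data_bits: str

    def __post_init__(self):
        if self.address < 0:
            raise ValueError("address must be non-negative")


# ---------------------------------------------------------------------------
# bit/trit conversion

def _parse_bits(bits: str) -> int:
    if bits == "":
        return 0
    if set(bits) - {"0", "1"}:
        raise ValueError(f"invalid bit string {bits!r}")
    return int(bits, 2)


def bits_to_trits(value_bits: str, width: int) -> str:
    """Big-endian base-3 representation of a bit string, zero-padded to ``width``."""
    value = _parse_bits(value_bits)
    if value >= 3**width:
        raise ValueError(f"value {value} does not fit in {width} trits")
    digits = []
    for _ in range(width):
        value, r = divmod(value, 3)
        digits.append(str(r))
    return "".join(reversed(digits))


def trits_to_bits(trits: str, nbits: int) -> str:
    """Inverse of :func:`bits_to_trits`; raises if the value overflows ``nbits``."""
    if set(trits) - {"0", "1", "2"}:
        raise ValueError(f"invalid trit string {trits!r}")
    value = 0
    for t in trits:
        value = value * 3 + int(t)
    if value >= 2**nbits:
        raise ValueError(f"trit value {value} does not fit in {nbits} bits")
    return format(value, f"0{nbits}b") if nbits else ""


# ---------------------------------------------------------------------------
# modulation

def modulate(trits: str, previous: str, table: TransitionTable) -> str:
    """Map a trit string to a transition sequence starting after ``previous``."""
    _check_base(previous)
    out = []
    prev = previous
    for t in trits:
        nxt = table.next_base(prev, int(t))
        out.append(nxt)
        prev = nxt
    return "".join(out)


def demodulate(seq: str, previous: str, table: TransitionTable) -> str:
    """Exact inverse of :func:`modulate`."""
    _check_base(previous)
    trits = []
    prev = previous
    for b in seq:
        trits.append(str(table.trit(prev, b)))
        prev = b
    return "".join(trits)


def build_scaffold(profile: CodecProfile) -> Scaffold:
    """Sync positions for a profile: one sync after every complete group of
    ``sync_period`` information nucleotides."""
    if profile.sync_period <= 0:
        return Scaffold(positions=())
    positions = []
    pos = 0
    info_seen = 0
    for _ in range(profile.n_info):
        pos += 1
        info_seen += 1
        if info_seen % profile.sync_period == 0:
            positions.append(pos)
            pos += 1
    if len(positions) != profile.n_sync or (positions and positions[-1] >= profile.K):
        raise ValueError("scaffold layout inconsistent with profile K")
    return Scaffold(positions=tuple(positions))


def _assemble_template(
    info_bases_trits: str, profile: CodecProfile, table: TransitionTable, label: str = ""
) -> TemplateSequence:
    scaffold = build_scaffold(profile)
    sync_positions = set(scaffold.positions)
    bases = []
    prev = profile.initiator_terminal
    it = iter(info_bases_trits)
    for pos in range(profile.K):
        if pos in sync_positions:
            nxt = scaffold.identity(pos, prev)
        else:
            nxt = table.next_base(prev, int(next(it)))
        bases.append(nxt)
        prev = nxt
    tail = ""
    if profile.terminal_c_tail:
        tail = "C"
    return TemplateSequence(
        bases="".join(bases),
        initiator_terminal=profile.initiator_terminal,
        ligation_tail=tail,
        label=label,
    )


def _strip_sync(bases: str, profile: CodecProfile) -> str:
    sync = set(build_scaffold(profile).positions)
    return "".join(b for i, b in enumerate(bases) if i not in sync)


def _info_trits_from_template(bases: str, profile: CodecProfile, table: TransitionTable) -> str:
    """Demodulate only the information positions; sync bases serve as context."""
    sync = set(build_scaffold(profile).positions)
    trits = []
    prev = profile.initiator_terminal
    for i, b in enumerate(bases):
        if i not in sync:
            trits.append(str(table.trit(prev, b)))
        prev = b
    return "".join(trits)


# ---------------------------------------------------------------------------
# ECC

def ecc_encode(info_bits: str, ecc_spec: str, omega: int | None = None, B: int | None = None) -> str:
    """Omega info bits -> B encoded bits (identity when ecc_spec == 'none')."""
    code = BCHCode.from_spec(ecc_spec, omega, B)
    if code is None:
        return info_bits
    return code.encode(info_bits)


def ecc_decode(
    encoded_bits: str, ecc_spec: str, omega: int | None = None, B: int | None = None
) -> tuple[str, int]:
    """B encoded bits -> (Omega info bits, number of corrected bit errors).

    Raises :class:`~transtore.bch.BCHDecodeFailure` on an uncorrectable block.
    """
    code = BCHCode.from_spec(ecc_spec, omega, B)
    if code is None:
        return encoded_bits, 0
    return code.decode(encoded_bits)


# ---------------------------------------------------------------------------
# message level

def _payload_to_records(payload: bytes, profile: CodecProfile) -> list[AddressedPayload]:
    data_bits = profile.data_bits
    if data_bits <= 0:
        raise CapacityError("profile has no data bits")
    bitstring = "".join(format(b, "08b") for b in payload)
    if len(bitstring) % data_bits:
        raise CapacityError(
            f"payload of {len(bitstring)} bits is not a multiple of {data_bits} data bits"
        )
    n_templates = len(bitstring) // data_bits
    if n_templates > 2**profile.address_bits:
        raise CapacityError(
            f"{n_templates} templates exceed the {2**profile.address_bits}-template address space"
        )
    return [
        AddressedPayload(address=i, data_bits=bitstring[i * data_bits : (i + 1) * data_bits])
        for i in range(n_templates)
    ]


def _record_to_trits(record: AddressedPayload, profile: CodecProfile) -> str:
    addr_bits = format(record.address, f"0{profile.address_bits}b") if profile.address_bits else ""
    info_bits = addr_bits + record.data_bits
    coded = ecc_encode(info_bits, profile.ecc_spec, profile.omega, profile.B)
    if profile.field_packing == "separate":
        aw, dw = profile._separate_widths()
        # address and data fields of the *coded* word are converted separately;
        # with no ECC the coded word is just address || data
        a = coded[: profile.address_bits]
        d = coded[profile.address_bits :]
        trits = bits_to_trits(a, aw) + bits_to_trits(d, dw)
        pad = profile.n_info - len(trits)
        return trits + "0" * pad if pad else trits
    return bits_to_trits(coded, profile.n_info)


def _trits_to_record(trits: str, profile: CodecProfile) -> tuple[AddressedPayload, int]:
    if profile.field_packing == "separate":
        aw, dw = profile._separate_widths()
        a = trits_to_bits(trits[:aw], profile.address_bits)
        d = trits_to_bits(trits[aw : aw + dw], profile.B - profile.address_bits)
        coded = a + d
    else:
        coded = trits_to_bits(trits, profile.B)
    info, n_corr = ecc_decode(coded, profile.ecc_spec, profile.omega, profile.B)
    address = int(info[: profile.address_bits], 2) if profile.address_bits else 0
    return AddressedPayload(address=address, data_bits=info[profile.address_bits :]), n_corr


def encode_message(
    payload: bytes, profile: CodecProfile, table: TransitionTable | None = None
) -> list[TemplateSequence]:
    """Encode a byte payload into one template sequence per addressed record."""
    if table is None:
        table = TransitionTable()
    records = _payload_to_records(payload, profile)
    out = []
    for rec in records:
        trits = _record_to_trits(rec, profile)
        label = f"{profile.name}:{rec.address:03d}"
        out.append(_assemble_template(trits, profile, table, label=label))
    return out


def decode_templates(
    sequences: Iterable[TemplateSequence | str],
    profile: CodecProfile,
    table: TransitionTable | None = None,
) -> bytes:
    """Invert :func:`encode_message`: demodulate, ECC-decode, reassemble by address."""
    if table is None:
        table = TransitionTable()
    records: dict[int, str] = {}
    duplicated = []
    for seq in sequences:
        bases = seq.bases if isinstance(seq, TemplateSequence) else str(seq)
        if len(bases) != profile.K:
            raise ValueError(f"sequence length {len(bases)} != profile K={profile.K}")
        trits = _info_trits_from_template(bases, profile, table)
        rec, _ = _trits_to_record(trits, profile)
        if rec.address in records:
            duplicated.append(rec.address)
        records[rec.address] = rec.data_bits
    n = len(records)
    missing = [a for a in range(n) if a not in records]
    if duplicated or missing or (records and max(records) != n - 1):
        extra = sorted(set(records) - set(range(n)))
        raise ReassemblyError(
            f"address reassembly failed (missing={missing}, duplicated={sorted(set(duplicated))}, "
            f"out-of-range={extra})",
            missing=missing,
            duplicated=duplicated,
        )
    bitstring = "".join(records[a] for a in range(n))
    if len(bitstring) % 8:
        raise ValueError("reassembled bit count is not a whole number of bytes")
    return bytes(int(bitstring[i : i + 8], 2) for i in range(0, len(bitstring), 8))


def capacity(bits_per_template: int, address_bits: int) -> tuple[int, float]:
    """(number of addressable templates, maximum stored bytes)."""
    if address_bits > bits_per_template:
        raise ValueError("address_bits must not exceed bits_per_template")
    n_templates = 2**address_bits
    max_bytes = n_templates * (bits_per_template - address_bits) / 8
    return n_templates, max_bytes


# ---------------------------------------------------------------------------
# built-in profiles

BUILTIN_PROFILES: dict[str, CodecProfile] = {
    # 12 x 8-nt templates carrying one ASCII character each behind a 4-bit
    # address; no ECC, no scaffold; address and data converted to base 3
    # separately (3 + 5 trits); polyC ligation tail appended after synthesis.
    "hello_world": CodecProfile(
        name="hello_world",
        K=8,
        B=12,
        omega=12,
        address_bits=4,
        sync_period=0,
        ecc_spec="none",
        initiator_terminal="G",
        field_packing="separate",
        terminal_c_tail=True,
    ),
    # 4 x 16-nt templates: 2-bit address + 14 data bits -> 12 info positions
    # + 4 sync nucleotides (one after every 3 info nucleotides).
    "eureka": CodecProfile(
        name="eureka",
        K=16,
        B=16,
        omega=16,
        address_bits=2,
        sync_period=3,
        ecc_spec="none",
        initiator_terminal="G",
    ),
    # scalable simulated systems; ECC per template
    "k38": CodecProfile(
        name="k38", K=38, B=33, omega=23, address_bits=11, sync_period=3,
        ecc_spec="bch-short(1023,1013,t=1)->(33,23)", initiator_terminal="G",
    ),
    "k74": CodecProfile(
        name="k74", K=74, B=63, omega=36, address_bits=15, sync_period=3,
        ecc_spec="bch(63,36,t=5)", initiator_terminal="G",
    ),
    "k152": CodecProfile(
        name="k152", K=152, B=128, omega=57, address_bits=15, sync_period=3,
        ecc_spec="bch-pad(127,57,t=11)+1", initiator_terminal="G",
    ),
}


def builtin_profile(name: str) -> CodecProfile:
    try:
        return BUILTIN_PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; available: {sorted(BUILTIN_PROFILES)}"
        ) from None
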