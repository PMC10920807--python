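"""Data-quality-flag (DQF) schemas and decoders.

Every ABI L2 product ships a per-pixel DQF.  Two kinds exist:

* *categorical* -- the flag value is a single quality level (CMI, Clear Sky
  Mask, AOD, DSR);
* *bit mask* -- an 8-bit integer whose individual bits (or small groups of
  bits) answer independent yes/no questions (BRF, LSA, Aerosol Detection,
  LST).

Bit numbering is least-significant bit = bit 0, so the BRF flag value 8 is
bit 3 set, 16 is bit 4, 24 is bits 3+4, 26 is bits 1+3+4.  Multi-bit fields
read the higher bit position as the more significant binary digit.

Schemas are declarative and ship as editable YAML files (one per product)
so users can correct or extend them without code changes.  The layouts for
the LSA, Aerosol Detection, and LST masks are provisional and flagged as
such in their files; the BRF layout and the printed decode of its four
observed values (8/16/24/26) are canonical.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

__all__ = [
    "BitField",
    "DQFSchema",
    "DecodedFlag",
    "load_schema",
    "available_schemas",
    "brf_schema",
    "decode_bitmask",
    "encode_bitmask",
    "snow_mask",
    "dsr_valid",
]


@dataclass(frozen=True)
class BitField:
    """One named field of a bit-mask flag.

    ``bit_positions`` lists the bits the field occupies, least significant
    first (bit 0 = least significant bit of the byte).
    """

    name: str
    bit_positions: tuple[int, ...]
    value_meanings: dict[int, str]

    def __post_init__(self) -> None:
        if not all(0 <= b <= 7 for b in self.bit_positions):
            raise ValueError(f"field {self.name}: bit positions must be in 0..7")
        if len(set(self.bit_positions)) != len(self.bit_positions):
            raise ValueError(f"field {self.name}: repeated bit position")

    def extract(self, value: int) -> int:
        out = 0
        for k, pos in enumerate(self.bit_positions):
            out |= ((value >> pos) & 1) << k
        return out

    def insert(self, field_value: int, into: int = 0) -> int:
        if not 0 <= field_value < (1 << len(self.bit_positions)):
            raise ValueError(
                f"field {self.name}: value {field_value} does not fit "
                f"{len(self.bit_positions)} bit(s)"
            )
        for k, pos in enumerate(self.bit_positions):
            into |= ((field_value >> k) & 1) << pos
        return into

    def label(self, field_value: int) -> str:
        return self.value_meanings.get(field_value, "unused")


@dataclass(frozen=True)
class DQFSchema:
    product_id: str
    kind: str  # "categorical" | "bitmask"
    fields: tuple[BitField, ...] = ()
    levels: dict[int, str] = field(default_factory=dict)
    usable_values: tuple[int, ...] = ()
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "bitmask"):
            raise ValueError(f"unknown DQF kind {self.kind!r}")
        if self.kind == "bitmask":
            if not self.fields or self.levels:
                raise ValueError("bitmask schema must define fields, not levels")
            seen: set[int] = set()
            for f in self.fields:
                overlap = seen.intersection(f.bit_positions)
                if overlap:
                    raise ValueError(f"bit positions {overlap} used by two fields")
                seen.update(f.bit_positions)
        else:
            if self.fields or not self.levels:
                raise ValueError("categorical schema must define levels, not fields")

    def field_named(self, name: str) -> BitField:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(f"{self.product_id}: no bit field named {name!r}")

    def to_dict(self) -> dict:
        d: dict = {"product_id": self.product_id, "kind": self.kind}
        if self.kind == "bitmask":
            d["fields"] = [
                {
                    "name": f.name,
                    "bits": list(f.bit_positions),
                    "meanings": {int(k): v for k, v in f.value_meanings.items()},
                }
                for f in self.fields
            ]
        else:
            d["levels"] = {int(k): v for k, v in self.levels.items()}
        if self.usable_values:
            d["usable_values"] = list(self.usable_values)
        if self.provisional:
            d["provisional"] = True
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DQFSchema":
        if d["kind"] == "bitmask":
            fields = tuple(
                BitField(
                    f["name"],
                    tuple(f["bits"]),
                    {int(k): v for k, v in f.get("meanings", {}).items()},
                )
                for f in d["fields"]
            )
            return cls(
                d["product_id"],
                "bitmask",
                fields=fields,
                usable_values=tuple(d.get("usable_values", ())),
                provisional=bool(d.get("provisional", False)),
            )
        return cls(
            d["product_id"],
            "categorical",
            levels={int(k): v for k, v in d["levels"].items()},
            usable_values=tuple(d.get("usable_values", ())),
            provisional=bool(d.get("provisional", False)),
        )


@dataclass(frozen=True)
class DecodedFlag:
    raw_value: int
    field_labels: dict[str, str]
    field_values: dict[str, int]
    usable_clear_sky_daytime: bool


def _schema_dir():
    return importlib.resources.files("abitower") / "schemas"


def available_schemas() -> list[str]:
    return sorted(p.name[:-5] for p in _schema_dir().iterdir() if p.name.endswith(".yaml"))


def load_schema(product_id: str) -> DQFSchema:
    """Load the shipped schema for a product (``brf``, ``dsr``, ``adp``...)."""
    path = _schema_dir() / f"{product_id.lower()}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"no shipped DQF schema for product {product_id!r}") from None
    return DQFSchema.from_dict(yaml.safe_load(text))


def brf_schema() -> DQFSchema:
    """The surface-reflectance (BRF) bit-mask schema."""
    return load_schema("brf")


def decode_bitmask(value: int, schema: DQFSchema) -> DecodedFlag:
    """Split an 8-bit flag into named fields with human-readable labels."""
    value = int(value)
    if not 0 <= value <= 255:
        raise ValueError(f"DQF value {value} outside 8-bit range")
    if schema.kind != "bitmask":
        raise ValueError(f"{schema.product_id} carries a categorical DQF")
    values = {f.name: f.extract(value) for f in schema.fields}
    labels = {f.name: f.label(values[f.name]) for f in schema.fields}
    usable = value in schema.usable_values
    return DecodedFlag(value, labels, values, usable)


def encode_bitmask(field_values: dict[str, int], schema: DQFSchema) -> int:
    """Inverse of :func:`decode_bitmask`: named field values -> raw byte."""
    raw = 0
    for f in schema.fields:
        raw = f.insert(field_values.get(f.name, 0), raw)
    return raw


def snow_mask(adp_dqf_value: int, schema: DQFSchema | None = None) -> bool:
    """True where the Aerosol Detection DQF reports snow/ice/cloud-invalid.

    The Aerosol Detection retrieval is invalidated over snow, ice, and
    cloud; that bit doubles as a snow-cover proxy for masking the NIRv
    family of indices.
    """
    if schema is None:
        schema = load_schema("adp")
    decoded = decode_bitmask(adp_dqf_value, schema)
    return decoded.field_values["snow_ice_cloud"] != 0


def dsr_valid(dsr_dqf_value) -> bool:
    """DSR usability: observations with DQF equal to 1 are invalid/degraded."""
    return int(dsr_dqf_value) != 1
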