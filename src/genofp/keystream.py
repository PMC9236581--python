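"""Keyed pseudorandom values shared by fingerprint insertion and extraction.

Two primitives:

* ``generate_fingerprint`` — the recipient-specific 128-bit string
  f_SP = MD5(K | n), where K is the owner's secret key and n the service
  provider's serial number.
* ``u_value`` — five domain-separated keyed pseudorandom channels
  U1..U5, realized as HMAC-SHA256 over "U<c>|token|token|..." and read as
  a big-endian integer.  Insertion and extraction call these with the
  same arguments, which is what makes blind extraction possible.

Neither primitive depends on any run-time RNG seed: the key alone
determines every selection.
"""

from __future__ import annotations

import hashlib
import hmac
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["OwnerKey", "FingerprintString", "generate_fingerprint", "u_value"]

FINGERPRINT_BITS = 128
_SEP = b"|"


class KeyError_(ValueError):
    """Empty or unusable owner key."""


@dataclass(frozen=True)
class OwnerKey:
    """The database owner's secret key K (never serialized to outputs)."""

    secret: bytes

    def __post_init__(self) -> None:
        if not isinstance(self.secret, (bytes, bytearray)) or len(self.secret) == 0:
            raise KeyError_("owner key must be a non-empty byte string")

    def __repr__(self) -> str:  # never leak the key in logs/tracebacks
        return "OwnerKey(<secret>)"


@dataclass(frozen=True)
class FingerprintString:
    """A length-L bit vector identifying one service provider."""

    bits: tuple[int, ...]
    sp_id: str

    @property
    def L(self) -> int:
        return len(self.bits)

    def as_array(self) -> np.ndarray:
        return np.array(self.bits, dtype=np.uint8)

    def hamming(self, other: "FingerprintString") -> int:
        if self.L != other.L:
            raise ValueError("fingerprint lengths differ")
        return int(np.sum(self.as_array() != other.as_array()))


def generate_fingerprint(key: OwnerKey, sp_id) -> FingerprintString:
    """f_SPn = MD5(K | n) expanded big-endian to 128 bits."""
    token = str(sp_id)
    if not token:
        raise ValueError("sp_id must render to a non-empty token")
    digest = hashlib.md5(key.secret + _SEP + token.encode("utf-8")).digest()
    bits = tuple(int(b) for b in np.unpackbits(np.frombuffer(digest, np.uint8)))
    assert len(bits) == FINGERPRINT_BITS
    return FingerprintString(bits=bits, sp_id=token)


def u_value(key: OwnerKey, channel: int, tokens: Sequence[str]) -> int:
    """Channel-c keyed pseudorandom integer over a token sequence.

    HMAC-SHA256(K, "U<c>|t1|t2|...") interpreted as a big-endian
    non-negative integer.  Deterministic in (K, channel, tokens).
    """
    if channel not in (1, 2, 3, 4, 5):
        raise ValueError(f"channel must be in 1..5, got {channel}")
    msg = _SEP.join(
        [b"U%d" % channel] + [str(t).encode("utf-8") for t in tokens]
    )
    return int.from_bytes(hmac.digest(key.secret, msg, "sha256"), "big")
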