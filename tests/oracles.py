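"""Independent reference implementations used only to check the package.

The SHA-1 here is a from-scratch implementation of the public algorithm
(RFC 3174) and the base64 encoder works directly on bit groups, so neither
shares any code path with the package under test.
"""

from __future__ import annotations

_B64_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789+/"


def _rotl(value: int, count: int) -> int:
    return ((value << count) | (value >> (32 - count))) & 0xFFFFFFFF


def sha1_reference(data: bytes) -> bytes:
    """RFC 3174 SHA-1, implemented independently of hashlib."""
    h = [0x67452301, 0xEFCDAB89, 0x98BADCFE, 0x10325476, 0xC3D2E1F0]
    message = bytearray(data)
    bit_len = len(data) * 8
    message.append(0x80)
    while len(message) % 64 != 56:
        message.append(0)
    message += bit_len.to_bytes(8, "big")
    for chunk_start in range(0, len(message), 64):
        w = [
            int.from_bytes(message[chunk_start + 4 * i: chunk_start + 4 * i + 4], "big")
            for i in range(16)
        ]
        for i in range(16, 80):
            w.append(_rotl(w[i - 3] ^ w[i - 8] ^ w[i - 14] ^ w[i - 16], 1))
        a, b, c, d, e = h
        for i in range(80):
            if i < 20:
                f, k = (b & c) | (~b & d), 0x5A827999
            elif i < 40:
                f, k = b ^ c ^ d, 0x6ED9EBA1
            elif i < 60:
                f, k = (b & c) | (b & d) | (c & d), 0x8F1BBCDC
            else:
                f, k = b ^ c ^ d, 0xCA62C1D6
            a, b, c, d, e = (
                (_rotl(a, 5) + f + e + k + w[i]) & 0xFFFFFFFF,
                a,
                _rotl(b, 30),
                c,
                d,
            )
        h = [(x + y) & 0xFFFFFFFF for x, y in zip(h, (a, b, c, d, e))]
    return b"".join(x.to_bytes(4, "big") for x in h)


def base64_reference(data: bytes) -> str:
    """Unpadded standard base64 built from 6-bit groups."""
    bits = "".join(f"{byte:08b}" for byte in data)
    chars = []
    for i in range(0, len(bits), 6):
        group = bits[i:i + 6].ljust(6, "0")
        chars.append(_B64_ALPHABET[int(group, 2)])
    return "".join(chars)


def rogid_reference(sequence: str, taxid: int) -> str:
    """Reference ROGID: unpadded base64(SHA-1(upper sequence)) + taxid."""
    cleaned = "".join(sequence.split()).upper()
    return base64_reference(sha1_reference(cleaned.encode())) + str(taxid)


def rigid_reference(rogid_strings: list[str]) -> str:
    """Reference RIGID from full ROGID strings."""
    joined = "".join(sorted(rogid_strings)).encode()
    return base64_reference(sha1_reference(joined))
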