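"""Deterministic seed derivation.

Every stage and subject draws from its own stream derived from one master
seed, so that re-running any subset of the pipeline reproduces identical
numbers and no two streams collide.
"""

import hashlib

_MOD = 2**31


def derive_seed(master: int, *parts: object) -> int:
    """Derive a sub-seed (< 2**31) from a master seed and context labels.

    The derivation hashes the decimal master seed together with the string
    forms of ``parts`` (stage name, subject index, ...) with SHA-256 and
    keeps the top four bytes.
    """
    token = "\x1f".join([str(int(master)), *map(str, parts)])
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % _MOD
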