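"""Lightweight call counters used by the ablation harness.

The ablation study must be able to prove that a disabled component is
truly bypassed, not merely neutralized; modules increment a named counter
on every call and the harness asserts zeros for switched-off components.
"""

from collections import Counter

counters: Counter = Counter()


def record(name: str) -> None:
    counters[name] += 1


def reset() -> None:
    counters.clear()


def count(name: str) -> int:
    return counters[name]
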