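"""Machine-readable run reports.

Every report is a JSON-serializable dict with a fixed shape: the payload
plus the tool version, the full parameter set (including any seed), and a
``metadata`` field holding the timestamp. Reruns with identical inputs and
seed are byte-identical outside ``metadata``.
"""

from __future__ import annotations

from datetime import datetime, timezone
from typing import Mapping

from . import __version__

__all__ = ["make_report", "sig6"]


def sig6(x: float) -> float:
    """Round to 6 significant digits for stable printed output."""
    return float(f"{x:.6g}")


def make_report(command: str, params: Mapping[str, object],
                payload: Mapping[str, object]) -> dict:
    return {
        "tool": "atbias",
        "version": __version__,
        "command": command,
        "params": dict(params),
        "result": dict(payload),
        "metadata": {
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    }
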