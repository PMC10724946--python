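"""Gene-set overlap enrichment (Fisher's exact test) and GMT I/O.

The one-sided Fisher exact test on a 2x2 overlap table reduces to the
hypergeometric upper tail; it is the workhorse behind module
preservation calls, PCPIC differential-signature enrichment, and
network-neighborhood driver scoring.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

from scipy import stats

__all__ = ["EnrichmentResult", "fisher_enrichment", "read_gmt", "write_gmt"]


@dataclass
class EnrichmentResult:
    query: str
    target: str
    overlap: int
    fold: float
    p: float
    fdr: float = float("nan")


def fisher_enrichment(
    query: set[str],
    target: set[str],
    universe: set[str],
    query_name: str = "query",
    target_name: str = "target",
) -> EnrichmentResult:
    """One-sided (upper tail) overlap enrichment of ``query`` in ``target``.

    Both sets are restricted to ``universe``.  ``fold`` is observed
    overlap divided by its expectation ``|q|*|t|/N``.  Empty query or
    target gives the degenerate p = 1, fold = 0 convention.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    n = len(universe)
    q = query & universe
    t = target & universe
    if not q or not t:
        return EnrichmentResult(query_name, target_name, 0, 0.0, 1.0)
    k = len(q & t)
    expected = len(q) * len(t) / n
    fold = k / expected if expected > 0 else 0.0
    # P(X >= k), X ~ Hypergeom(N=n, K=|t|, draws=|q|)
    p = float(stats.hypergeom.sf(k - 1, n, len(t), len(q)))
    return EnrichmentResult(query_name, target_name, k, fold, min(max(p, 0.0), 1.0))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file (name, description, tab-separated genes)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> Path:
    """Write gene sets to GMT; genes sorted for reproducible bytes."""
    path = Path(path)
    lines = [
        "\t".join([name, description] + sorted(map(str, genes)))
        for name, genes in sorted(sets.items())
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path
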