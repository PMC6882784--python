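"""Read-count quality filters and spatial categorization of mutations.

Discovery calls from exome sequencing pass when the discovery region has
coverage >= 10, at least 3 variant reads, VAF >= 1% and at least one
variant read on each strand.  Validation by targeted amplicon sequencing
(higher coverage, higher base error) requires, each in at least one tumor
region: VAF >= 1%, variant reads >= 5, forward variant reads >= 3 and
reverse variant reads >= 3 — the four criteria may be satisfied in
different regions.  Validated mutations (excluding the initiating knock-in
transgene mutations) are categorized as ubiquitous, partially shared or
private according to how many of the analyzed tumor regions they are
present in.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "discovery_filter",
    "validation_filter",
    "is_present",
    "categorize_heterogeneity",
]


def discovery_filter(
    depth: int,
    var: int,
    fwd: int,
    rev: int,
    min_depth: int = 10,
    min_var: int = 3,
    min_vaf: float = 0.01,
) -> bool:
    """Exome discovery filter for one candidate call in one region."""
    if var > depth or fwd + rev != var or min(depth, var, fwd, rev) < 0:
        raise ValueError("inconsistent read counts")
    vaf = var / depth if depth > 0 else 0.0
    return depth >= min_depth and var >= min_var and vaf >= min_vaf and fwd >= 1 and rev >= 1


def validation_filter(
    region_counts: dict[str, tuple[int, int, int, int]],
    min_vaf: float = 0.01,
    min_var: int = 5,
    min_strand: int = 3,
) -> bool:
    """Targeted-sequencing validation across all tumor regions.

    ``region_counts`` maps region id to ``(depth, var, fwd, rev)``.  A call
    is validated when each criterion — VAF >= ``min_vaf``, variant reads
    >= ``min_var``, forward variant reads >= ``min_strand`` and reverse
    variant reads >= ``min_strand`` — holds in at least one region (not
    necessarily the same region for every criterion).
    """
    ok_vaf = ok_var = ok_fwd = ok_rev = False
    for depth, var, fwd, rev in region_counts.values():
        if var > depth or fwd + rev != var or min(depth, var, fwd, rev) < 0:
            raise ValueError("inconsistent read counts")
        vaf = var / depth if depth > 0 else 0.0
        ok_vaf |= vaf >= min_vaf
        ok_var |= var >= min_var
        ok_fwd |= fwd >= min_strand
        ok_rev |= rev >= min_strand
    return ok_vaf and ok_var and ok_fwd and ok_rev


def is_present(depth: int, var: int, min_vaf: float = 0.01, min_var: int = 3) -> bool:
    """Per-region presence rule: VAF >= 1% and at least 3 variant reads."""
    vaf = var / depth if depth > 0 else 0.0
    return var >= min_var and vaf >= min_vaf


def categorize_heterogeneity(
    mutations: pd.DataFrame,
    regions: list[str],
    min_vaf: float = 0.01,
    min_var: int = 3,
) -> pd.Series:
    """Classify each validated, non-transgene mutation by spatial spread.

    ``mutations`` carries per-region count columns ``tot_<region>`` and
    ``var_<region>`` plus a boolean ``is_transgene`` column; ``regions``
    lists the analyzed tumor regions only (excluded regions shrink the
    denominator for "all analyzed samples").  Returns a Series with values
    ``ubiquitous`` (present in all analyzed regions), ``partially_shared``
    (in more than one but not all), ``private`` (exactly one), ``absent``
    (none), and ``transgene`` for knock-in mutations.
    """
    if not regions:
        raise ValueError("no analyzed regions")
    out = []
    for row in mutations.itertuples(index=False):
        if getattr(row, "is_transgene", False):
            out.append("transgene")
            continue
        n_present = sum(
            is_present(getattr(row, f"tot_{r}"), getattr(row, f"var_{r}"), min_vaf, min_var)
            for r in regions
        )
        if n_present == 0:
            out.append("absent")
        elif n_present == len(regions):
            out.append("ubiquitous")
        elif n_present == 1:
            out.append("private")
        else:
            out.append("partially_shared")
    return pd.Series(out, index=mutations.index, name="heterogeneity")
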