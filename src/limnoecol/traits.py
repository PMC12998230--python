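"""Taxonomy-pattern functional-trait inference (FAPROTAX-style).

A trait database is an ordered list of groups; each group has a name,
``key:value`` metadata, member patterns (glob strings where ``*`` matches
any run of characters, semicolons included, anchored at both ends,
case-sensitive), and optional ``add_group:`` lines that union in the
patterns of an earlier group.  A taxon matches a trait when its
semicolon-joined lineage matches any of the group's (expanded) patterns;
trait abundance per sample is the sum of matching taxa's absolute
abundances in cells/ml.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from ._errors import InvalidConfigError, ParseError

__all__ = [
    "TraitGroup",
    "TraitDatabase",
    "TraitAbundance",
    "parse_trait_db",
    "parse_trait_db_text",
    "match_taxonomy",
    "trait_abundance",
]


@dataclass
class TraitGroup:
    name: str
    metadata: dict = field(default_factory=dict)
    patterns: list = field(default_factory=list)
    add_groups: list = field(default_factory=list)


@dataclass
class TraitDatabase:
    groups: list  # ordered TraitGroup list

    def group_names(self):
        return [g.name for g in self.groups]

    def expanded_patterns(self, name: str) -> list:
        """Member patterns of a group with add_group references expanded."""
        by_name = {g.name: g for g in self.groups}
        if name not in by_name:
            raise InvalidConfigError(f"unknown trait group {name!r}")
        seen = []

        def expand(n):
            g = by_name[n]
            pats = list(g.patterns)
            for ref in g.add_groups:
                if ref not in seen:
                    seen.append(ref)
                    pats.extend(expand(ref))
            return pats

        return expand(name)


def parse_trait_db_text(text: str) -> TraitDatabase:
    groups: list[TraitGroup] = []
    known: set[str] = set()
    current = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        stripped = line.strip()
        if stripped.startswith("add_group:"):
            ref = stripped[len("add_group:"):].strip()
            if current is None:
                raise ParseError(f"line {lineno}: add_group before any group")
            if ref not in known:
                raise ParseError(
                    f"line {lineno}: add_group references unknown or later "
                    f"group {ref!r}"
                )
            current.add_groups.append(ref)
            continue
        tokens = stripped.split()
        # headers carry key:value metadata (or are a bare name without
        # glob/rank characters); everything else is a member pattern
        if len(tokens) > 1 and all(":" in t for t in tokens[1:]):
            meta = dict(t.split(":", 1) for t in tokens[1:])
            current = TraitGroup(name=tokens[0], metadata=meta)
            groups.append(current)
            known.add(current.name)
        elif len(tokens) == 1 and not ("*" in stripped or ";" in stripped):
            current = TraitGroup(name=tokens[0])
            groups.append(current)
            known.add(current.name)
        else:
            if current is None:
                raise ParseError(f"line {lineno}: member pattern before any group")
            current.patterns.append(stripped)
    return TraitDatabase(groups=groups)


def parse_trait_db(path) -> TraitDatabase:
    with open(path, encoding="utf-8") as fh:
        return parse_trait_db_text(fh.read())


def _pattern_re(pattern: str):
    return re.compile(".*".join(re.escape(p) for p in pattern.split("*")))


def match_taxonomy(tax_string: str, pattern: str) -> bool:
    """Anchored, case-sensitive glob match; ``*`` crosses rank separators."""
    return _pattern_re(pattern).fullmatch(tax_string) is not None


@dataclass
class TraitAbundance:
    values_df: pd.DataFrame  # trait x sample, cells/ml
    contributors: dict  # trait -> sorted taxon list
    coverage: float  # fraction of taxa matching >= 1 trait


def trait_abundance(db: TraitDatabase, tax, abund) -> TraitAbundance:
    """Per-sample trait abundances in cells/ml.

    ``tax`` is a :class:`~limnoecol.features.TaxonomyTable`; ``abund`` must
    be an absolute-mode abundance matrix.  A taxon may contribute to any
    number of traits; coverage is the fraction of matrix taxa with at
    least one trait.
    """
    if getattr(abund, "mode", "absolute") != "absolute":
        raise InvalidConfigError("trait inference requires an absolute-mode matrix")
    values = abund.values_df
    lineages = tax.lineages().reindex(values.index).fillna("")
    rows, contributors = {}, {}
    matched_any = pd.Series(False, index=values.index)
    for g in db.groups:
        pats = [_pattern_re(p) for p in db.expanded_patterns(g.name)]
        if pats:
            mask = lineages.map(lambda s: any(p.fullmatch(s) for p in pats))
        else:
            mask = pd.Series(False, index=values.index)
        matched_any |= mask
        contributors[g.name] = sorted(values.index[mask])
        rows[g.name] = values[mask].sum(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "trait"
    return TraitAbundance(
        values_df=out,
        contributors=contributors,
        coverage=float(matched_any.mean()) if len(matched_any) else 0.0,
    )
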