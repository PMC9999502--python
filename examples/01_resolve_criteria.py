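"""Harmonize the nine explicit PIM criteria into comparable ATC code sets.

Loads the packaged synthetic criteria summary, resolves every criterion
(statement filtering -> class expansion -> market screening) and prints the
summary counts and cross-criteria consensus substances.
"""

from pimscreen import (
    consensus_count,
    pre_screen_summary,
    reference_criteria,
    resolve_all,
)
from pimscreen.synthetic_criteria import SUBSTANCE_NAMES

criteria, formulary = reference_criteria()
criteria = list(criteria)
sets = resolve_all(criteria, list(formulary))

pre = pre_screen_summary(criteria)
union = frozenset().union(*(s.resolved_codes for s in sets.values()))
print(f"harmonized summary: {len(pre)} ATC codes before the market screen")
print(f"marketed PIMs:      {len(union)} ATC codes after the market screen\n")

print("PIMs identified per criterion:")
for cid, cs in sets.items():
    print(f"  {cid:10s} {len(cs.resolved_codes):4d}")

print("\nsubstances listed by most criteria (consensus count / 9):")
ranked = sorted(union, key=lambda c: (-consensus_count(c, sets.values()), c))
for code in ranked[:11]:
    n = consensus_count(code, sets.values())
    print(f"  {code}  {SUBSTANCE_NAMES.get(code, ''):16s} {n}/9")

# The counts mirror a national comparison of nine criteria: a few old
# psychotropics are universal PIMs, while most codes are criterion-specific.
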