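"""Category counts for the packaged printed co-expression lists.

Loads the published co-expression partner lists of the two strongest
candidates (queries SvMYB24 and SvMYB74), applies the r >= 0.85 screening
threshold, and counts partners per functional category. The totals are the
"n target genes" that drive the shortlist rule (pass at >= 11).
"""

import mybfunnel as mf
from mybfunnel.coexpr import printed_annotation, printed_records

annotation = printed_annotation()
for query in ("SvMYB24", "SvMYB74"):
    records = [r for r in printed_records(query) if r.r >= 0.85]
    _, counts = mf.count_target_categories(records, annotation)
    print(f"{query}: {len(records)} partners at r >= 0.85, "
          f"r range {min(r.r for r in records):.3f}-{max(r.r for r in records):.3f}")
    for category, n in counts.per_category.items():
        print(f"  {category:25s} {n}")
    print(f"  flags: {', '.join(k for k, v in counts.flags.items() if v)}")
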