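"""The similarity-search engine: saturation and the sensitive fallback.

Shows (1) recursive widening of the target cap when many references tie
at the top score — the full equal-score stratum is what downstream
species-complex calling consumes — and (2) the sensitive rerun that
recovers a distant relative the fast seeded pass misses.
"""

import numpy as np

from fintax.search import DbEntry, SequenceDatabase, recursive_top_hits, search_with_fallback

rng = np.random.default_rng(0)
bases = np.array(list("ACGT"))
dna = lambda n: "".join(rng.choice(bases, size=n))

query = dna(150)

# 12 identical references + one slightly worse: a naive top-10 search
# would truncate the tie, hiding two of the co-equal species
entries = [DbEntry(f"ref{i:02d}", query) for i in range(12)]
worse = list(query)
worse[10] = "A" if query[10] != "A" else "C"
entries.append(DbEntry("worse", "".join(worse)))
stratum, saturated = recursive_top_hits(query, SequenceDatabase(entries))
print(f"tied top hits: {len(stratum)} (saturated={saturated})")

# a relative at ~92% identity shares no 28-mer with the query, so the
# fast pass finds nothing and the 11-mer sensitive pass takes over
relative = list(dna(156))
template = "".join(relative)
for p in range(6, 156, 13):
    relative[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[relative[p]]
db = SequenceDatabase([DbEntry("relative", "".join(relative))])
hits, _ = search_with_fallback(template, db)
print(f"fallback found: {hits[0].subject_id} at {hits[0].identity:.1f}% identity")
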