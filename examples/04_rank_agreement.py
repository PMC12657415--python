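"""The top-k agreement metrics on a worked pair of rankings.

Rankings (a, b, c, d, e) and (a, f, g, d, e) share three features — a, d, e
— all at identical positions, and the union of the two top-5 sets has seven
members, so both Jaccard similarity and union-normalized Rank Agreement
equal 3/7.  Swapping two positions lowers Rank Agreement but not Jaccard.
"""

from explainstab import TopKRanking, jaccard_top_k, rank_agreement

r1 = TopKRanking(features=("a", "b", "c", "d", "e"), k=5)
r2 = TopKRanking(features=("a", "f", "g", "d", "e"), k=5)
print(f"jaccard({r1.features} vs {r2.features}) = {jaccard_top_k(r1, r2):.4f}  (3/7)")
print(f"rank_agreement(same pair)                = {rank_agreement(r1, r2):.4f}  (3/7)")

r3 = TopKRanking(features=("a", "b", "c", "e", "d"), k=5)  # d and e swapped
print(f"\nafter swapping the last two positions of ranking 1:")
print(f"jaccard        = {jaccard_top_k(r1, r3):.4f}  (same sets)")
print(f"rank_agreement = {rank_agreement(r1, r3):.4f}  (3 of 5 positions agree)")
# Rank Agreement can never exceed Jaccard: its numerator counts a subset of
# the intersection over the same union denominator.
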