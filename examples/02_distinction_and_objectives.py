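"""The worked example: a 7-feature distinction table and both objectives.

Uses the bundled toy table (two classes of 2 and 3 samples, hence 6
inter-class pairs) to show how a candidate subset is scored.
"""

from swarmselect import (
    cardinality,
    covered_rows,
    evaluate_pair,
    is_reduct,
    toy_distinction_table,
    weighted_fitness,
)

table = toy_distinction_table()
print(f"distinction table: {table.n_rows} pairs x {table.n_features} features")
print(table.to_frame().to_string())

v = (1, 0, 1, 1, 0, 1, 1)
pair = evaluate_pair(v, table)
print(f"\nsubset v={v}")
print(f"  cardinality O_v = {cardinality(v)} of N = {table.n_features}")
print(f"  discerned pairs R_v = {covered_rows(table, v)} of {table.n_rows}")
print(f"  Fit1 = (N - O_v)/N = {pair.fit1:.4f}   (parsimony)")
print(f"  Fit2 = R_v/(C1*C2) = {pair.fit2:.4f}   (discerning power)")
print(f"  weighted sum (alpha=0.5) = {weighted_fitness(pair, 0.5):.4f}")
print(f"  reduct (covers every pair)? {is_reduct(table, v)}")

# v leaves one sample pair undiscerned, so it is not a reduct: Fit2 < 1.
# Dropping useless features raises Fit1 without touching Fit2.
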