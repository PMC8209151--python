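"""Disease semantic similarity from MeSH-style tree numbers.

Each disease is placed in the MeSH hierarchy by dot-separated tree numbers;
ancestors contribute semantic weight that halves per generation.  Diseases
sharing deep ancestors score high; diseases from different branches score 0.
"""

from mdlink import (
    contribution,
    dag_from_tree_numbers,
    disease_similarity_matrix,
    semantic_value,
)

table = {
    "breast carcinoma": ["C04.588.180"],
    "lung carcinoma": ["C04.588.894"],
    "lymphoma": ["C04.557.386"],
    "hypertension": ["C14.907.489"],
}

dags = dag_from_tree_numbers(table)
cmap = contribution(dags["breast carcinoma"])
print("semantic contributions for breast carcinoma:")
for term, value in sorted(cmap.items(), key=lambda kv: -kv[1]):
    print(f"  {term:14s} {value:.2f}")
print(f"semantic value DV = {semantic_value(cmap):.2f} "
      "(the disease counts 1, each ancestor generation half as much)")

mat = disease_similarity_matrix(dags)
print("\npairwise semantic similarity:")
print(mat.round(3))
print("\nthe two carcinomas share C04.588 and score highest; lymphoma shares "
      "only the C04 root; hypertension shares nothing and scores 0.")
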