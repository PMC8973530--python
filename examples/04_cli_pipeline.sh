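#!/usr/bin/env bash
# Full pipeline from the shell: simulate -> fit -> transform -> evaluate.
# Every command writes a JSON manifest beside its outputs (config, seed,
# SHA-256 checksums), so a run is reproducible from its manifest alone.
set -euo pipefail

dir=$(mktemp -d)
echo "working in $dir"

wordmanifold simulate --out-dir "$dir/fx" --n-words 400 --ambient-dim 20 \
    --n-pairs 80 --seed 3

wordmanifold fit --embeddings "$dir/fx/embeddings.glove.txt" --format glove \
    --window-size 300 --neighbors 12 --seed 3 --out "$dir/model.wmm"

wordmanifold transform --embeddings "$dir/fx/embeddings.glove.txt" --format glove \
    --model "$dir/model.wmm" --out "$dir/reembedded.txt"

echo "--- raw embedding ---"
wordmanifold evaluate --embeddings "$dir/fx/embeddings.glove.txt" --format glove \
    --dataset "$dir/fx/similarity.csv"
echo "--- re-embedded ---"
wordmanifold evaluate --embeddings "$dir/reembedded.txt" --format glove \
    --dataset "$dir/fx/similarity.csv"

# parameter study: one evaluation row per neighbor count k
echo "--- k sweep ---"
wordmanifold evaluate --embeddings "$dir/fx/embeddings.glove.txt" --format glove \
    --dataset "$dir/fx/similarity.csv" --sweep-k 8,12,16 --window-size 300 --seed 3
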