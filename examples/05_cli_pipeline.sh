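#!/bin/sh
# End-to-end shell pipeline: simulate two experiments, pool them in one
# inference, and run the self-designing workflow.
set -e
mkdir -p scratch/example
cd scratch/example

# 1. simulate 10 noisy progress curves at scarce and excess enzyme
tqkin simulate --fixture test_enzyme --et 0.2 --st 0.2 --n-curves 10 \
      --seed 1 --out low.csv
tqkin simulate --fixture test_enzyme --et 40  --st 0.2 --n-curves 10 \
      --seed 2 --out high.csv

# 2. pooled joint inference with the tQ likelihood
tqkin infer --model tq --data low.csv --data high.csv \
      --iterations 10000 --seed 3 \
      --prior-mean-kcat 1 --prior-mean-km 2 --out draws.csv
python -c "import json; s=json.load(open('draws.csv.summary.json')); \
p=s['parameters']; print('k_cat', p['k_cat']['mean'], 'K_M', p['K_M']['mean'])"

# 3. the sequential design loop, fully automated
tqkin design --fixture test_enzyme --n-curves 10 --iterations 10000 \
      --seed 4 --out audit.json
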