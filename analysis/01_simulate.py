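"""Generate the synthetic study inputs: posts, sentiment dictionary, embeddings.

Writes to results/data/ in the same formats a real study would consume
(JSONL posts, LIWC-style .dic, word2vec text), plus a manifest with the
planted ground truth needed by the later stages' recovery summaries.
"""

import argparse
import json
from pathlib import Path

from discoursetrends.corpus import write_posts_jsonl
from discoursetrends.synthcorpus import default_spec, generate_corpus, generate_dictionary, generate_embeddings
from discoursetrends.wordvec import write_word2vec


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    spec = default_spec(seed=args.seed)
    posts, truth = generate_corpus(spec)
    write_posts_jsonl(posts, args.outdir / "posts.jsonl")
    generate_dictionary(spec, args.outdir / "dictionary.dic")
    write_word2vec(generate_embeddings(spec), args.outdir / "embeddings.txt")

    manifest = {
        "seed": args.seed,
        "T": spec.T,
        "K_true": spec.K_true,
        "n_posts": len(posts),
        "n_docs_per_quarter": truth.n_docs_per_quarter,
        "prevalence": truth.prevalence.tolist(),
        "sentiment_expected": truth.sentiment_expected,
        "doc_dominant": truth.doc_dominant,
    }
    with open(args.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    print(f"wrote {len(posts)} posts across {spec.T} quarters "
          f"({sum(truth.n_docs_per_quarter)} pooled documents, K_true={spec.K_true})")
    print(f"inputs + ground-truth manifest in {args.outdir}/")


if __name__ == "__main__":
    main()
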