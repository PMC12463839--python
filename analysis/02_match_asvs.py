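"""Match ASVs against the culture-collection region databases.

Reads the FASTA written by 01_simulate_data.py, runs the ungapped
aligner over every region database, applies the 2-nt length rule and the
merged > 27F > 515F > 515R preference, and writes the collated match
table, per-isolate summaries (>= 95% identity) and a match-rate report.
"""

import argparse
from pathlib import Path

from rhizoscreen import matching


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results") / "synthetic")
    ap.add_argument("--out", type=Path, default=Path("results") / "matching")
    ap.add_argument("--min-identity", type=float, default=95.0)
    ap.add_argument("--max-len-diff", type=int, default=2)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    asvs = matching.read_asv_fasta(args.data / "sequences" / "asvs.fasta")
    records = []
    for region in matching.REGIONS:
        records.extend(matching.read_reference_fasta(
            args.data / "sequences" / f"refs_{region}.fasta"))
    index = matching.build_reference_index(records)
    hits = matching.match_asvs(asvs, index)
    table = matching.collate_matches(
        hits, {a: len(s) for a, s in asvs.items()},
        max_len_diff=args.max_len_diff)
    table.to_tsv(args.out / "match_table.tsv")
    summaries, report = matching.summarize_isolates(
        table, min_identity=args.min_identity)
    matching.summaries_to_frame(summaries).to_csv(
        args.out / "isolate_summaries.tsv", sep="\t", index=False)
    (args.out / "match_report.txt").write_text(
        "\n".join(f"{k}: {v}" for k, v in sorted(report.items())) + "\n")

    ids = [s.best_percent_identity for s in summaries]
    print(f"{report['n_matched_asvs']}/{report['n_total_asvs']} ASVs "
          f"({100 * report['fraction_matched']:.0f}%) matched "
          f"{report['n_matched_isolates']} isolates; best identities "
          f"span {min(ids):.3f}-{max(ids):.3f}%")


if __name__ == "__main__":
    main()
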