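{
  "EML4-ALK": {
    "hg38": {
      "comment": "Published detection windows: EML4 reads are scanned, ALK is the mate window.",
      "five_prime": {"chrom": "chr2", "start": 42169353, "end": 42332548, "strand": "+", "label": "EML4"},
      "three_prime": {"chrom": "chr2", "start": 29192774, "end": 29921586, "strand": "-", "label": "ALK"}
    },
    "hg19": {
      "comment": "Derived windows: hg38 values lifted to hg19 (UCSC gene spans); not published, override via a config file if needed.",
      "five_prime": {"chrom": "chr2", "start": 42396490, "end": 42559688, "strand": "+", "label": "EML4"},
      "three_prime": {"chrom": "chr2", "start": 29415640, "end": 30144432, "strand": "-", "label": "ALK"}
    }
  }
}
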