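{
 "divergence_times.tsv": "246861e2729a20bca61ba0ce48e611c1b704bed55a31b87f73c48e13abd1b455",
 "lambda_catalog.tsv": "3a9a073bb75f1bb975970f76cc5fdb8df7605e219b17f1aafe2fc67074cb447b",
 "table1.tsv": "fa26b82b0925167655eb53834f76fe21962438966526419ff3d7c20000527863",
 "table2.tsv": "dbb629db271c34401d1d90284de7789e2381c05aec976149ed13ac2c379ce95f",
 "table3.tsv": "80c0ec54efbb55b69f38e9f8870ba8fb0b1b4f0f60229181708f9d79c6450e8a"
}
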