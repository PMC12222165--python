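{
 "hd_schema.yaml": "4875fa84b7ef2686ed0a70eaa923487b8bed51e2c8c5888bd0e7b59ba07cdcad",
 "stack_performance_table3.csv": "5c630a47a1345a545b362bf5f20bf0bae37ba18a16e197336407fd248f2c2384",
 "stack_performance_table3.directions.yaml": "60f1a16983a1545d2884552fd867153b903c979657c2ab66e4f5f5cadf9bdf3a",
 "table4_weights.csv": "ce9ec3f78590ffe196db3032fcb93edc3ab87cb53ad3344f29d6d6f460dba536"
}
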