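{
  "config_hash": "f536b1343dc12ffb3462bd2a098c10b060e3e2e77808610b1c22ebab4e98650b",
  "files": {
    "classifier_reports.json": "31e040c10413a4ac59239cf9e1c39558e9240180a15c43b8960273c46b13a229",
    "classifier_summary.csv": "499a1766fc378da0a581be56520a4a309e48f73fd1adc28aa19a38fc3f9ae49a",
    "clinical.csv": "b56061ac98bf7c6b836aff9b96590e738ef8aa04295ff20026963a99466c3167",
    "glm_comparisons.csv": "530695ef71128d7bcb3c47b83bc2f6379ae6e09a58ac529fd106fa339e0dcbaa",
    "glm_fits.json": "426858a10fe4f7efd7f9009ee00d854e16325c2f1060048f54e03a9dedacf7b9",
    "normative_demographics.csv": "d2f064d36240b7c4b2b82ea8a5b1bd948b5f52e5e866fa304eb4c0683513ef4c",
    "normative_thickness.csv": "9f686fcd98e5a948113248620d52e3b78db4b9274da37235e04cb25b263d2518",
    "patch_stats.csv": "00d5e4d10ebc16865aeb35db8e15d14518443cb0319fe68e78ab4228498f0ee0",
    "patient_demographics.csv": "6fce2a9816a4ea3b8bc58c7b03fbb19f75226c06fecaeef4a1ab74c63e4fac5b",
    "patient_thickness.csv": "2ab60d998be48d7f315768f7621873fad963fac0d5de04cec8993c80f55a6923",
    "progression_labels.csv": "19253f7f6040148772e553db5bfe794f6d4e41120af9c096e93ceb0798261991",
    "tpf.csv": "5e27dada86b050e617cab74f51032555f2214fcf7d7224758a2ae97559e23587",
    "truth.json": "702f0e1e980aa8f91d6edbe550c43af255561394982eee52eb6d537d09b34945",
    "wilcoxon.csv": "6d98a1635ba40286cf8209a6d79e074794867fb2b9c5f2af9bd753efaaeb3f64",
    "z_scores.csv": "87110965e0b9fcc7b0aab59cd7dfe7f3f1e30ed3924a6bf592148fe96185d06b"
  }
}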