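{
 "shoot_dry_weight.csv": "2867c1b3aeeabcc34a13fbf843c33c529929c0ac244796b97f633d15ee0fa55b",
 "tuber_yield.csv": "253cb007f3f267c3069465d0dabab21c7a8beb37cfb5512b4d2a87fd3adf7add"
}
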