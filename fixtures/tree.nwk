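(((sp01:0.40563555147149394,sp02:0.40563555147149394):0.2982537812421216,((((((sp03:0.005444089752993008,sp04:0.005444089752993008):0.00953087130171891,sp05:0.014974961054711921):0.18157312217867863,sp06:0.19654808323339054):0.24745053735903103,(sp07:0.06380355489276371,sp08:0.06380355489276371):0.3801950656996579):0.13441721595044406,(sp09:0.42936557697430516,((sp10:0.06385056685727208,sp11:0.06385056685727208):0.3471478427827832,(sp12:0.06368117661222517,sp13:0.06368117661222517):0.34731723302783013):0.018367167334249868):0.14905025956856052):0.042341991664630686,(sp14:0.24586609489492695,(sp15:0.1932746354757623,sp16:0.1932746354757623):0.05259145941916462):0.3748917333125694):0.08313150450611911):0.29567260808045587,sp17:0.9995619407940711):0.00043805920592850713;
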