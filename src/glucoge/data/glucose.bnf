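# Glucose-forecasting grammar. Non-terminals are bracketed; productions are
# separated by `|`; λ is the empty production. Whitespace is insignificant.
# Each Get* call carries its lag window (PrevIni, PrevFin), the operator and
# unary pre-operator chain of the term, and the two constants of the term:
# the divisor α and the offset δ, both drawn from the [Cte] rule.
[Body]      ::= ExprG^=([G][op][Ra][op][IOB])[op][Circadian]
[G]         ::= GetG([PrevIni],[PrevFin],[op],[preop],[Cte],[Cte])[G] | λ
[Ra]        ::= GetRa([PrevIni],[PrevFin],[op],[preop],[Cte],[Cte])[Ra] | λ
[IOB]       ::= GetIOB([PrevIni],[PrevFin],[op],[preop],[Cte],[Cte])[IOB] | λ
[preop]     ::= sqrt | sin | log | pow | exp | cos | [preop][preop] | λ
[Circadian] ::= GetCircadian([OpB],[Cte],[Cte],[Cte]) | λ
[Cte]       ::= ([Dgt][Dgt].[Dgt])
[op]        ::= [OpA] | [OpB]
[PrevIni]   ::= 0 | 1 | 2 | 4 | 6 | 8 | 10 | 12 | 14 | 16 | 18 | 20 | 22
[PrevFin]   ::= 1 | 2 | 4 | 6 | 8 | 10 | 12 | 14 | 16 | 18 | 20 | 22 | 24
[Dgt]       ::= 0 | 1 | 2 | 3 | 4 | 5 | 6 | 7 | 8 | 9
[OpA]       ::= + | -
[OpB]       ::= / | *
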