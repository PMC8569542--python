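(* Eligibility-criteria expression language — EBNF *)
(* Precedence, loosest to tightest:
   or < and < not < comparison < "+"|"-" < "*"|"/" < unary "-" < "^"      *)

start        = definition | expr ;
definition   = IDENT ":=" expr ;

expr         = or_expr ;
or_expr      = and_expr { "or" and_expr } ;
and_expr     = not_expr { "and" not_expr } ;
not_expr     = "not" not_expr | comparison ;

(* one operator -> binary comparison; two or more -> chained comparison;
   chain operators mix "=" with one direction of {"<","<="} or {">",">="} *)
comparison   = sum { cmp_op sum } ;
cmp_op       = "<" | "<=" | ">" | ">=" | "=" | "!=" ;

sum          = term { ("+" | "-") term } ;
term         = factor { ("*" | "/") factor } ;
factor       = "-" factor | power ;
power        = postfix [ "^" factor ] ;            (* right-associative *)

postfix      = primary { "." attribute
                       | "." collection_fn "(" ")" } ;
attribute    = "StartTime" | "EndTime" | "Value" ;
collection_fn= "count" | "max" | "min" | "first" | "last" ;

primary      = NUMBER | DURATION | STRING | "true" | "false"
             | free_fn "(" [ expr { "," expr } ] ")"
             | concept_ref
             | "(" expr ")" ;
free_fn      = "attached"            (* arity 1: any record of the concept *)
             | "diff"                (* arity 2: signed time difference    *)
             | "contains"            (* arity 2: free-text containment     *)
             | "current_date_time" ; (* arity 0: injectable clock          *)

concept_ref  = IDENT | "[" BRACKETED_NAME "]" ;    (* interchangeable      *)

IDENT        = /[A-Za-z_][A-Za-z0-9_]*/ ;          (* not a keyword        *)
BRACKETED_NAME = /[^\]\n]+/ ;
NUMBER       = /\d+(\.\d+)?([eE][+-]?\d+)?/ ;
STRING       = /"[^"\n]*"/ ;
DURATION     = ISO-8601 duration, e.g. PT48H, P2W, P1Y
               (fixed-length calendar units: 1Y = 365.25 d, 1M = 30.4375 d) ;
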